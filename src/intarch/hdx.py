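"""HDX-MS deuteration-change tables, significance filtering and protection maps.

Negative Δ%D means protection (slower exchange upon complex formation);
positive Δ%D means increased solvent accessibility.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HDXPeptide",
    "ProtectionMap",
    "HDXError",
    "parse_hdx_table",
    "filter_significant",
    "residue_protection_map",
    "interface_enrichment_test",
]


class HDXError(ValueError):
    pass


@dataclass(frozen=True)
class HDXPeptide:
    """Peptide-level Δ%D at the 15 s and/or 120 s timepoints."""

    protein: str
    start: int
    end: int  # inclusive
    sequence: str
    delta_15s: float | None = None
    delta_120s: float | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise HDXError(f"peptide {self.start}-{self.end}: end < start")
        if self.sequence and len(self.sequence) != self.end - self.start + 1:
            raise HDXError(
                f"peptide {self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start + 1}"
            )
        if self.delta_15s is None and self.delta_120s is None:
            raise HDXError(f"peptide {self.start}-{self.end}: no Δ%D value at any timepoint")

    @property
    def deltas(self) -> list[float]:
        return [d for d in (self.delta_15s, self.delta_120s) if d is not None]

    @property
    def representative_delta(self) -> float:
        """The largest-magnitude timepoint value."""
        return max(self.deltas, key=abs)

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class ProtectionMap:
    """Per-residue protection scores projected from peptide-level Δ%D."""

    protein: str
    scores: dict[int, float] = field(default_factory=dict)  # residue -> signed Δ%D
    coverage: dict[int, int] = field(default_factory=dict)  # residue -> peptide count

    def covered_residues(self) -> list[int]:
        return sorted(self.scores)

    def score(self, residue: int) -> float | None:
        """Signed protection score, or None where there is no peptide coverage."""
        return self.scores.get(residue)


# ---------------------------------------------------------------------------
# Parsing

def _normalize(text: str) -> str:
    return text.replace("−", "-").replace("—", "-").replace(" ", " ")


_RANGE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)\*?$")


def _parse_range(token: str) -> tuple[int, int]:
    m = _RANGE.match(_normalize(token).strip())
    if not m:
        raise HDXError(f"malformed residue range token {token!r}")
    return int(m.group(1)), int(m.group(2))


def _parse_delta(token: str) -> float | None:
    token = token.strip()
    if not token:
        return None
    return float(_normalize(token))


def _read_text(path_or_text: str | Path) -> str:
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    if path_or_text.strip() and "\n" not in path_or_text:
        try:
            candidate = Path(path_or_text)
            if candidate.is_file():
                return candidate.read_text()
        except OSError:
            pass
    return path_or_text


def parse_hdx_table(path_or_text: str | Path, dialect: str = "paper_table") -> list[HDXPeptide]:
    """Parse an HDX Δ%D peptide table.

    ``paper_table``: tab-delimited blocks, each introduced by a bare protein
    name, rows ``start–end<TAB>SEQUENCE<TAB>Δ%D15[<TAB>Δ%D120]`` with Unicode
    minus/en-dash tolerated and either timepoint cell possibly empty.

    ``csv``: columns protein,start,end,sequence,delta_15s,delta_120s.
    """
    text = _read_text(path_or_text)
    if dialect == "csv":
        return _parse_csv(text)
    if dialect != "paper_table":
        raise HDXError(f"unknown dialect {dialect!r}")

    peptides: list[HDXPeptide] = []
    protein = None
    for raw in text.splitlines():
        if not raw.strip():
            continue
        line = raw.rstrip("\n")
        if line.strip().startswith("*") or line.lower().startswith("residue"):
            continue  # caption row
        cells = line.split("\t")
        if len(cells) == 1:
            protein = cells[0].strip()
            continue
        if protein is None:
            raise HDXError("peptide row encountered before any protein block header")
        if len(cells) < 3:
            raise HDXError(f"malformed row: {raw!r}")
        start, end = _parse_range(cells[0])
        sequence = cells[1].strip()
        delta_15 = _parse_delta(cells[2])
        delta_120 = _parse_delta(cells[3]) if len(cells) > 3 else None
        peptides.append(
            HDXPeptide(protein, start, end, sequence, delta_15, delta_120)
        )
    return peptides


def _parse_csv(text: str) -> list[HDXPeptide]:
    stripped = text.strip()
    if not stripped:
        return []
    delim = "\t" if "\t" in stripped.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(stripped), delimiter=delim)
    out = []
    for row in reader:
        row = {k.strip(): (v or "").strip() for k, v in row.items() if k}
        out.append(
            HDXPeptide(
                protein=row["protein"],
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=row.get("sequence", ""),
                delta_15s=_parse_delta(row.get("delta_15s", "")),
                delta_120s=_parse_delta(row.get("delta_120s", "")),
            )
        )
    return out


def write_hdx_csv(peptides: list[HDXPeptide], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein", "start", "end", "sequence", "delta_15s", "delta_120s"])
        for p in peptides:
            writer.writerow(
                [
                    p.protein, p.start, p.end, p.sequence,
                    "" if p.delta_15s is None else f"{p.delta_15s:g}",
                    "" if p.delta_120s is None else f"{p.delta_120s:g}",
                ]
            )


# ---------------------------------------------------------------------------
# Filtering and mapping

def filter_significant(
    peptides: list[HDXPeptide], threshold: float = 7.0
) -> tuple[list[HDXPeptide], list[HDXPeptide]]:
    """Split peptides into (protected, deprotected) by |Δ%D| ≥ threshold.

    The sign of the largest-magnitude timepoint decides the list, so a
    peptide appears in at most one of the two.
    """
    if threshold <= 0:
        raise HDXError("threshold must be positive")
    protected, deprotected = [], []
    for p in peptides:
        rep = p.representative_delta
        if abs(rep) < threshold:
            continue
        (protected if rep < 0 else deprotected).append(p)
    return protected, deprotected


def residue_protection_map(peptides: list[HDXPeptide]) -> ProtectionMap:
    """Project peptide Δ%D onto residues.

    Each residue's score is the unweighted mean over all spanning peptides of
    the peptide's largest-magnitude timepoint value; coverage counts spanning
    peptides. Residues with no coverage are absent (explicit no-data).
    """
    if not peptides:
        raise HDXError("no peptides to map")
    proteins = {p.protein for p in peptides}
    if len(proteins) > 1:
        raise HDXError(f"peptides from multiple proteins: {sorted(proteins)}")
    totals: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p in peptides:
        rep = p.representative_delta
        for residue in p.residues:
            totals[residue] = totals.get(residue, 0.0) + rep
            counts[residue] = counts.get(residue, 0) + 1
    scores = {res: totals[res] / counts[res] for res in totals}
    return ProtectionMap(protein=proteins.pop(), scores=scores, coverage=counts)


# ---------------------------------------------------------------------------
# Interface enrichment

def interface_enrichment_test(
    protection_map: ProtectionMap,
    interface_residues: set[int],
    n_permutations: int = 10_000,
    seed: int = 0,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Permutation test for protection enrichment at an interface.

    Statistic: mean score over interface residues minus mean over covered
    non-interface residues (more negative = stronger protection at the
    interface). One-sided p-value by permuting residue scores among covered
    residues: p = (1 + #{permuted ≤ observed}) / (n_permutations + 1).
    """
    if not interface_residues:
        raise HDXError("interface residue set is empty")
    covered = protection_map.covered_residues()
    uncovered_iface = interface_residues - set(covered)
    if uncovered_iface:
        raise HDXError(f"interface residues without coverage: {sorted(uncovered_iface)[:5]}")
    scores = np.array([protection_map.scores[r] for r in covered])
    is_iface = np.array([r in interface_residues for r in covered])
    n_iface = int(is_iface.sum())
    if n_iface == len(covered):
        return 0.0, 1.0

    def statistic(values: np.ndarray) -> float:
        return float(values[is_iface].mean() - values[~is_iface].mean())

    observed = statistic(scores)
    rng = np.random.default_rng(seed)
    count_le = 0
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(scores)
        stat = statistic(perm)
        if stat <= observed:
            count_le += 1
        if stat >= observed:
            count_ge += 1
    p_low = (1 + count_le) / (n_permutations + 1)
    if two_sided:
        p_high = (1 + count_ge) / (n_permutations + 1)
        return observed, min(1.0, 2.0 * min(p_low, p_high))
    return observed, p_low
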