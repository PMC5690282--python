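"""Cross-link spectrum-match handling and distance restraints.

Parses CSM tables, collapses them to unique residue-pair links, builds
chemistry-aware Cα–Cα distance restraints against an assembly and evaluates
their satisfaction on models.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULT_CHEMISTRY, ChemistryParams
from .structures import Assembly, StructureError

__all__ = [
    "CrosslinkCSM",
    "UniqueLink",
    "DistanceRestraint",
    "SatisfactionReport",
    "CLMSError",
    "parse_csm_table",
    "deduplicate_links",
    "build_restraints",
    "evaluate_satisfaction",
    "restraint_energy",
]


class CLMSError(ValueError):
    pass


ResidueSite = tuple[str, int]  # (one-letter residue type, author number)


def _normalize(text: str) -> str:
    """Fold Unicode minus/dash variants and exotic whitespace to ASCII."""
    return (
        text.replace("−", "-")
        .replace("–", "-")
        .replace("—", "-")
        .replace(" ", " ")
        .replace("﻿", "")
    )


_RESIDUE_TOKEN = re.compile(r"^([A-Za-z])(\d+)$")


def parse_residue_token(token: str) -> ResidueSite:
    """'K97' -> ('K', 97)."""
    m = _RESIDUE_TOKEN.match(token.strip())
    if not m:
        raise CLMSError(f"malformed residue token {token!r}")
    return (m.group(1).upper(), int(m.group(2)))


@dataclass(frozen=True)
class CrosslinkCSM:
    """One spectrum-level identification of a cross-linked residue pair."""

    protein_a: str
    residue_a: ResidueSite
    protein_b: str
    residue_b: ResidueSite
    score: float
    chemistry: str = "BS3"
    decoy: bool = False  # set by the simulator; never consulted by docking

    def __post_init__(self) -> None:
        if self.residue_a[1] <= 0 or self.residue_b[1] <= 0:
            raise CLMSError("residue numbers must be positive integers")
        if self.score < 0:
            raise CLMSError(f"negative score {self.score}")

    @property
    def canonical_pair(self) -> tuple[tuple[str, str, int], tuple[str, str, int]]:
        """Unordered pair identity: (protein, res type, res number) sorted."""
        ends = (
            (self.protein_a, *self.residue_a),
            (self.protein_b, *self.residue_b),
        )
        return tuple(sorted(ends))  # type: ignore[return-value]


@dataclass(frozen=True)
class UniqueLink:
    """A unique residue pair with its CSM support."""

    pair: tuple[tuple[str, str, int], tuple[str, str, int]]
    n_matches: int
    highest_score: float
    chemistry: str = "BS3"
    decoy: bool = False


@dataclass
class DistanceRestraint:
    """A residue-pair distance restraint resolved against assembly chains."""

    site_a: tuple[str, int]  # (chain, author residue number)
    site_b: tuple[str, int]
    target: float  # Å
    upper_bound: float  # Å, satisfaction cutoff
    lower_bound: float = 0.0
    weight: float = 1.0
    chemistry: str = "BS3"
    link: UniqueLink | None = None

    def __post_init__(self) -> None:
        if not (self.lower_bound <= self.target <= self.upper_bound):
            raise CLMSError("restraint requires lower_bound <= target <= upper_bound")
        if self.weight <= 0:
            raise CLMSError("restraint weight must be positive")


# ---------------------------------------------------------------------------
# Parsing

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


_BLOCK_HEADER = re.compile(r"^([A-Za-z0-9_/]+)-([A-Za-z0-9_/]+)$")
_SUMMARY_LINE = re.compile(r"^\(\d+ unique links?\)")


def parse_csm_table(
    path_or_text: str | Path, dialect: str = "csv", chemistry: str = "BS3"
) -> list[CrosslinkCSM]:
    """Parse a cross-link table into CSMs.

    ``csv`` dialect: delimited columns
    protein_a,residue_a,protein_b,residue_b,score[,chemistry].

    ``paper_table`` dialect: block layout with a ``PROTA-PROTB`` header per
    block, one grouped row per unique pair carrying a match count and the
    highest score; each row is expanded into ``n_matches`` CSMs so counts
    are recoverable after deduplication.
    """
    text = _normalize(_read_text(path_or_text))
    if dialect == "paper_table":
        return _parse_paper_table(text, chemistry)
    if dialect == "csv":
        return _parse_csv(text)
    raise CLMSError(f"unknown dialect {dialect!r}")


def _parse_paper_table(text: str, chemistry: str) -> list[CrosslinkCSM]:
    csms: list[CrosslinkCSM] = []
    prot_a = prot_b = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or _SUMMARY_LINE.match(line):
            continue
        header = _BLOCK_HEADER.match(line)
        if header:
            prot_a, prot_b = header.group(1), header.group(2)
            continue
        if line.startswith("*") or line.lower().startswith("residue"):
            continue  # column caption row
        fields = line.split()
        if len(fields) < 4:
            raise CLMSError(f"malformed row: {raw!r}")
        if prot_a is None:
            raise CLMSError("data row encountered before a PROTA-PROTB block header")
        res_a = parse_residue_token(fields[0])
        res_b = parse_residue_token(fields[1])
        try:
            n_matches = int(fields[2])
            score = float(fields[3])
        except ValueError as exc:
            raise CLMSError(f"malformed row: {raw!r}") from exc
        for _ in range(n_matches):
            csms.append(
                CrosslinkCSM(prot_a, res_a, prot_b, res_b, score, chemistry=chemistry)
            )
    return csms


def _parse_csv(text: str) -> list[CrosslinkCSM]:
    stripped = text.strip()
    if not stripped:
        return []
    delim = "\t" if "\t" in stripped.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(stripped), delimiter=delim)
    csms = []
    for row in reader:
        row = {k.strip(): (v or "").strip() for k, v in row.items() if k}
        csms.append(
            CrosslinkCSM(
                protein_a=row["protein_a"],
                residue_a=parse_residue_token(row["residue_a"]),
                protein_b=row["protein_b"],
                residue_b=parse_residue_token(row["residue_b"]),
                score=float(row["score"]),
                chemistry=row.get("chemistry") or "BS3",
                decoy=row.get("decoy", "").lower() in ("1", "true", "yes"),
            )
        )
    return csms


def write_csm_csv(csms: list[CrosslinkCSM], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["protein_a", "residue_a", "protein_b", "residue_b", "score", "chemistry"]
        )
        for c in csms:
            writer.writerow(
                [
                    c.protein_a,
                    f"{c.residue_a[0]}{c.residue_a[1]}",
                    c.protein_b,
                    f"{c.residue_b[0]}{c.residue_b[1]}",
                    f"{c.score:g}",
                    c.chemistry,
                ]
            )


# ---------------------------------------------------------------------------
# Deduplication

def deduplicate_links(csms: list[CrosslinkCSM]) -> list[UniqueLink]:
    """Collapse CSMs to unique unordered residue-pair links.

    Output is sorted by highest score descending, ties broken
    lexicographically on the canonical pair.
    """
    groups: dict[tuple, list[CrosslinkCSM]] = {}
    for csm in csms:
        groups.setdefault((csm.canonical_pair, csm.chemistry), []).append(csm)
    links = [
        UniqueLink(
            pair=pair,
            n_matches=len(members),
            highest_score=max(m.score for m in members),
            chemistry=chemistry,
            decoy=any(m.decoy for m in members),
        )
        for (pair, chemistry), members in groups.items()
    ]
    links.sort(key=lambda l: (-l.highest_score, l.pair))
    return links


# ---------------------------------------------------------------------------
# Restraints

def build_restraints(
    links: list[UniqueLink],
    assembly: Assembly,
    chain_map: dict[str, str],
    chemistry_params: dict[str, ChemistryParams] | None = None,
    residue_offsets: dict[str, int] | None = None,
    score_weighting: bool = False,
) -> tuple[list[DistanceRestraint], list[UniqueLink]]:
    """Resolve links against an assembly; unmappable links are returned, not dropped.

    ``chain_map`` maps protein labels to chain IDs; ``residue_offsets`` maps
    protein labels to the offset added to table residue numbers to obtain
    author numbering in the structures (e.g. full-length vs. core numbering).
    """
    params = chemistry_params or DEFAULT_CHEMISTRY
    offsets = residue_offsets or {}
    restraints: list[DistanceRestraint] = []
    unmappable: list[UniqueLink] = []
    for link in links:
        if link.chemistry not in params:
            raise CLMSError(f"no chemistry parameters for {link.chemistry!r}")
        p = params[link.chemistry]
        sites = []
        ok = True
        for protein, _restype, number in link.pair:
            if protein not in chain_map:
                raise CLMSError(f"unknown protein label {protein!r} (not in chain map)")
            chain = chain_map[protein]
            author_number = number + offsets.get(protein, 0)
            try:
                assembly.ca_coord(chain, author_number)
            except StructureError:
                ok = False
                break
            sites.append((chain, author_number))
        if not ok:
            unmappable.append(link)
            continue
        weight = max(link.highest_score, 1e-3) if score_weighting else 1.0
        restraints.append(
            DistanceRestraint(
                site_a=sites[0],
                site_b=sites[1],
                target=p.target,
                upper_bound=p.upper_bound,
                weight=weight,
                chemistry=link.chemistry,
                link=link,
            )
        )
    return restraints, unmappable


@dataclass
class SatisfactionReport:
    """Per-restraint distances and the overall satisfaction fraction."""

    records: list[dict] = field(default_factory=list)
    fraction: float = 0.0

    @property
    def n_satisfied(self) -> int:
        return sum(1 for r in self.records if r["satisfied"])

    def to_dict(self) -> dict:
        return {
            "n_restraints": len(self.records),
            "n_satisfied": self.n_satisfied,
            "fraction_satisfied": self.fraction,
            "restraints": self.records,
        }


def evaluate_satisfaction(
    assembly: Assembly, restraints: list[DistanceRestraint]
) -> SatisfactionReport:
    """Cα–Cα distance per restraint; satisfied ⇔ distance ≤ upper bound."""
    if not restraints:
        raise CLMSError("satisfaction fraction undefined for empty restraint list")
    records = []
    for r in restraints:
        d = float(
            np.linalg.norm(
                assembly.ca_coord(*r.site_a) - assembly.ca_coord(*r.site_b)
            )
        )
        records.append(
            {
                "site_a": list(r.site_a),
                "site_b": list(r.site_b),
                "distance": d,
                "upper_bound": r.upper_bound,
                "chemistry": r.chemistry,
                "satisfied": bool(d <= r.upper_bound),
            }
        )
    fraction = sum(1 for rec in records if rec["satisfied"]) / len(records)
    return SatisfactionReport(records=records, fraction=fraction)


def restraint_energy(
    distance: np.ndarray | float,
    target: np.ndarray | float,
    upper_bound: np.ndarray | float,
    weight: np.ndarray | float = 1.0,
) -> np.ndarray | float:
    """Flat-bottom harmonic with a linear cap.

    Zero for d ≤ target, (d − target)² up to the upper bound, then continued
    linearly with the slope at the bound so outliers (decoy links) have
    bounded influence.
    """
    d = np.asarray(distance, dtype=float)
    excess = np.clip(d - target, 0.0, None)
    quad_span = upper_bound - target
    quad = np.minimum(excess, quad_span) ** 2
    linear = 2.0 * quad_span * np.clip(d - upper_bound, 0.0, None)
    out = weight * (quad + linear)
    return float(out) if np.isscalar(distance) else out
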