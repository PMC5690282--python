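"""Orthogonal validation computations.

Solvent-accessible surface areas and buried interface areas, native-MS
stoichiometry inference by exhaustive mass arithmetic, NSAF relative
abundances, and the consolidated model-quality report.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Assembly, Structure, StructureError

__all__ = [
    "SASAResult",
    "StoichiometrySolution",
    "NSAFTable",
    "ValidationError",
    "VDW_RADII",
    "sasa",
    "interface_area",
    "infer_stoichiometry",
    "nsaf",
    "quality_report",
]


class ValidationError(ValueError):
    pass


#: Bondi-style van der Waals radii (Å), fixed for reproducibility.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "ZN": 1.39, "MG": 1.73, "FE": 1.40, "CA": 2.31, "NA": 2.27, "K": 2.75,
}


@dataclass
class SASAResult:
    areas: np.ndarray  # Å² per atom
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(np.sum(self.areas))


@dataclass
class StoichiometrySolution:
    copies: dict[str, int]
    predicted_mass: float  # Da
    residual: float  # Da, predicted − observed

    def to_dict(self) -> dict:
        return {
            "copies": self.copies,
            "predicted_mass": self.predicted_mass,
            "residual": self.residual,
        }


@dataclass
class NSAFTable:
    rows: list[dict] = field(default_factory=list)  # protein, spectral_count, length, nsaf

    def value(self, protein: str) -> float:
        for row in self.rows:
            if row["protein"] == protein:
                return row["nsaf"]
        raise ValidationError(f"no protein {protein!r} in NSAF table")


# ---------------------------------------------------------------------------
# Surface areas

def _spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _atoms_of(obj: Structure | Assembly) -> tuple[np.ndarray, list[str]]:
    structure = obj.flatten() if isinstance(obj, Assembly) else obj
    coords, elements = [], []
    for residues in structure.chains.values():
        for res in residues:
            for a in res.atoms:
                coords.append(a.coord)
                elements.append(a.element.upper())
    return np.array(coords), elements


def sasa(
    obj: Structure | Assembly,
    probe: float = 1.4,
    n_points: int = 960,
    uniform_radius: float | None = None,
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    Deterministic: test points come from a fixed golden-spiral set. For
    Cα-only models pass ``uniform_radius`` (e.g. 3.0 Å) since bare carbon
    radii under-represent whole residues.
    """
    coords, elements = _atoms_of(obj)
    if len(coords) == 0:
        raise ValidationError("no atoms")
    if uniform_radius is not None:
        radii = np.full(len(coords), float(uniform_radius))
    else:
        unknown = sorted({e for e in elements if e not in VDW_RADII})
        if unknown:
            raise ValidationError(f"unknown element(s): {unknown}")
        radii = np.array([VDW_RADII[e] for e in elements])
    extended = radii + probe
    sphere = _spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + extended[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= extended[j]
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * extended[i] ** 2 * accessible.sum() / n_points
    return SASAResult(areas=areas, probe_radius=probe, n_points=n_points)


def interface_area(
    assembly: Assembly,
    part_a: list[str],
    part_b: list[str],
    probe: float = 1.4,
    n_points: int = 960,
    uniform_radius: float | None = None,
) -> float:
    """Buried interface area (SASA(A) + SASA(B) − SASA(A∪B)) / 2 in Å²."""
    if set(part_a) & set(part_b):
        raise ValidationError("parts must be disjoint")
    if not part_a or not part_b:
        raise ValidationError("each part must contain at least one component")

    def part_structure(labels: list[str]) -> Structure:
        comps = [assembly[label] for label in labels]
        return Assembly(comps).flatten()

    kwargs = {"probe": probe, "n_points": n_points, "uniform_radius": uniform_radius}
    area_a = sasa(part_structure(part_a), **kwargs).total
    area_b = sasa(part_structure(part_b), **kwargs).total
    area_ab = sasa(part_structure(part_a + part_b), **kwargs).total
    return (area_a + area_b - area_ab) / 2.0


# ---------------------------------------------------------------------------
# Mass spectrometry arithmetic

def infer_stoichiometry(
    component_masses: dict[str, float],
    complex_mass: float,
    tolerance: float,
    max_copies: int = 4,
) -> list[StoichiometrySolution]:
    """All copy-number vectors whose summed mass matches the complex mass.

    Exhaustive search over [0, max_copies] per component; solutions sorted by
    absolute residual, ties by copy vector.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    labels = sorted(component_masses)
    for label in labels:
        if component_masses[label] <= 0:
            raise ValidationError(f"non-positive mass for {label!r}")
    solutions = []
    for copies in itertools.product(range(max_copies + 1), repeat=len(labels)):
        if sum(copies) == 0:
            continue
        predicted = sum(n * component_masses[l] for n, l in zip(copies, labels))
        residual = predicted - complex_mass
        if abs(residual) <= tolerance:
            solutions.append(
                StoichiometrySolution(
                    copies=dict(zip(labels, copies)),
                    predicted_mass=float(predicted),
                    residual=float(residual),
                )
            )
    solutions.sort(key=lambda s: (abs(s.residual), tuple(s.copies.values())))
    return solutions


def nsaf(counts: dict[str, tuple[float, int]]) -> NSAFTable:
    """Normalized spectral abundance factors: (SpC/L) / Σ(SpC/L)."""
    if not counts:
        raise ValidationError("empty count table")
    saf = {}
    for protein, (spc, length) in counts.items():
        if length <= 0:
            raise ValidationError(f"{protein}: length must be positive")
        if spc < 0:
            raise ValidationError(f"{protein}: negative spectral count")
        saf[protein] = spc / length
    total = sum(saf.values())
    if total <= 0:
        raise ValidationError("all spectral counts are zero")
    table = NSAFTable(
        rows=[
            {
                "protein": protein,
                "spectral_count": counts[protein][0],
                "length": counts[protein][1],
                "nsaf": saf[protein] / total,
            }
            for protein in sorted(counts)
        ]
    )
    return table


# ---------------------------------------------------------------------------
# Consolidated report

_REPORT_KEYS = (
    "software_version",
    "seed",
    "config",
    "refinement",
    "satisfaction",
    "saxs",
    "hdx_enrichment",
    "interface_areas",
)


def quality_report(
    refinement: dict,
    satisfaction: dict | None = None,
    saxs: dict | None = None,
    hdx_enrichment: dict | None = None,
    interface_areas: dict | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble the consolidated model-quality report (JSON-serializable).

    Deterministic: serializing the same inputs twice yields byte-identical
    documents (sorted keys, no timestamps).
    """
    from . import __version__

    if refinement is None:
        raise ValidationError("a refinement result is required")
    report = {
        "software_version": __version__,
        "seed": seed,
        "config": config or {},
        "refinement": refinement,
        "satisfaction": satisfaction,
        "saxs": saxs,
        "hdx_enrichment": hdx_enrichment,
        "interface_areas": interface_areas,
    }
    _validate_report(report)
    return report


def _validate_report(report: dict) -> None:
    missing = [k for k in _REPORT_KEYS if k not in report]
    if missing:
        raise ValidationError(f"report missing keys: {missing}")
    json.dumps(report)  # must be serializable


def report_json(report: dict) -> str:
    _validate_report(report)
    return json.dumps(report, indent=2, sort_keys=True)
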