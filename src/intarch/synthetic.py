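"""Ground-truth synthetic fixtures for end-to-end pipeline validation.

Generates toy two-domain complexes with a known inter-domain pose,
cross-link tables with controlled decoy fractions, Debye-based SAXS curves
with Gaussian noise, and HDX tables whose interface-overlapping peptides
carry negative Δ%D shifts. Every generator is a pure function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .clms import CrosslinkCSM
from .config import DEFAULT_CHEMISTRY
from .hdx import HDXPeptide
from .saxs import SAXSCurve, debye_profile
from .structures import (
    Assembly,
    AssemblyComponent,
    Atom,
    Residue,
    RigidTransform,
    Structure,
)

__all__ = [
    "Scenario",
    "SyntheticError",
    "CHAIN_MAP",
    "make_toy_complex",
    "simulate_crosslinks",
    "simulate_saxs",
    "simulate_hdx",
]


class SyntheticError(RuntimeError):
    pass


#: Protein-label → chain-ID map used by all synthetic fixtures.
CHAIN_MAP: dict[str, str] = {"REC": "A", "MOB": "B"}

_STEP = 3.8  # Å, consecutive Cα spacing
_MIN_SEP = 4.0  # Å, non-bonded clash floor


@dataclass
class Scenario:
    """Fully serializable description of one synthetic ground-truth dataset."""

    seed: int = 2017
    receptor_size: int = 100
    mobile_size: int = 80
    n_links: int = 20
    decoy_fraction: float = 0.1
    chemistry: str = "BS3"
    saxs_noise: float = 0.02
    hdx_effect: float = -15.0
    hdx_coverage: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.decoy_fraction < 1.0):
            raise SyntheticError("decoy_fraction must be in [0, 1)")
        if min(self.receptor_size, self.mobile_size) < 20:
            raise SyntheticError("domain sizes must be >= 20 residues")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Scenario":
        return cls(**json.loads(text))

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent per-generator RNG streams split from the scenario seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("structure", "links", "saxs", "hdx")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Toy complex construction

def _compact_walk(n: int, rng: np.random.Generator, max_restarts: int = 60) -> np.ndarray:
    """Self-avoiding Cα walk with a compactness bias toward Rg ≈ 2.2·n^0.38 Å."""
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        direction = rng.normal(size=3)
        coords.append(_STEP * direction / np.linalg.norm(direction))
        failed = False
        while len(coords) < n:
            i = len(coords)
            target_rg = 2.2 * i**0.38
            arr = np.array(coords)
            dirs = rng.normal(size=(48, 3))
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
            candidates = coords[-1] + _STEP * dirs
            # self-avoidance against all but the immediate predecessor
            dmin = np.min(
                np.linalg.norm(candidates[:, None, :] - arr[None, :-1, :], axis=2), axis=1
            )
            valid = candidates[dmin >= _MIN_SEP]
            if len(valid) == 0:
                failed = True
                break
            # pick the candidate whose inclusion tracks the target Rg best
            center = arr.mean(axis=0)
            new_centers = (center * i + valid) / (i + 1)
            best, best_err = None, np.inf
            for cand, nc in zip(valid, new_centers):
                sq = np.sum((np.vstack([arr, cand]) - nc) ** 2, axis=1)
                err = abs(np.sqrt(sq.mean()) - target_rg)
                if err < best_err:
                    best, best_err = cand, err
            coords.append(best)
        if not failed:
            return np.array(coords)
    raise SyntheticError(
        f"self-avoiding walk failed for n={n}; try a different size or seed"
    )


def _ca_structure(coords: np.ndarray, id: str, chain: str) -> Structure:
    residues = [
        Residue(i + 1, "", "ALA", [Atom("CA", "C", c.copy())]) for i, c in enumerate(coords)
    ]
    return Structure(id, {chain: residues})


def _contact_walk(
    n: int,
    receptor: np.ndarray,
    rng: np.random.Generator,
    max_restarts: int = 60,
) -> np.ndarray:
    """Compact self-avoiding walk grown against the receptor surface.

    Keeps every Cα at least 4 Å from the receptor while preferring to stay
    within ~9 Å of it, producing a tightly packed, shape-complementary
    interface (the steric signature real complexes have, which makes the
    true pose identifiable by clash + restraint scoring alone).
    """
    surface_pull = 9.0  # Å, drift penalty starts beyond this receptor distance
    # anchor at a distal surface point so the assembly stays elongated and
    # far-apart (decoy-eligible) residue pairs exist
    radial = np.linalg.norm(receptor - receptor.mean(axis=0), axis=1)
    distal = np.argsort(radial)[::-1][:10]
    for _ in range(max_restarts):
        anchor = receptor[distal[rng.integers(len(distal))]]
        outward = anchor - receptor.mean(axis=0)
        outward /= max(np.linalg.norm(outward), 1e-9)
        start = anchor + (_MIN_SEP + 1.0) * outward
        if np.linalg.norm(receptor - start, axis=1).min() < _MIN_SEP:
            continue
        coords = [start]
        failed = False
        while len(coords) < n:
            i = len(coords)
            target_rg = 0.9 * 2.2 * i**0.38  # bulge term re-inflates toward 2.2·n^0.38
            arr = np.array(coords)
            dirs = rng.normal(size=(48, 3))
            dirs /= np.linalg.norm(dirs, axis=1)[:, None]
            candidates = coords[-1] + _STEP * dirs
            if i >= 2:
                dmin_self = np.min(
                    np.linalg.norm(candidates[:, None, :] - arr[None, :-1, :], axis=2), axis=1
                )
            else:
                dmin_self = np.full(len(candidates), np.inf)
            dmin_rec = np.min(
                np.linalg.norm(candidates[:, None, :] - receptor[None, :, :], axis=2), axis=1
            )
            mask = (dmin_self >= _MIN_SEP) & (dmin_rec >= _MIN_SEP)
            if not mask.any():
                failed = True
                break
            valid = candidates[mask]
            valid_rec = dmin_rec[mask]
            center = arr.mean(axis=0)
            new_centers = (center * i + valid) / (i + 1)
            cost = np.empty(len(valid))
            for k, (cand, nc) in enumerate(zip(valid, new_centers)):
                sq = np.sum((np.vstack([arr, cand]) - nc) ** 2, axis=1)
                cost[k] = abs(np.sqrt(sq.mean()) - target_rg)
            if i < (3 * n) // 5:  # pack the first 60% against the receptor
                cost += 0.7 * np.clip(valid_rec - surface_pull, 0.0, None)
            else:  # let the rest bulge away so distal (decoy-eligible) pairs exist
                radial_pos = np.linalg.norm(valid - receptor.mean(axis=0), axis=1)
                cost += 0.12 * np.clip(38.0 - radial_pos, 0.0, None)
            coords.append(valid[int(np.argmin(cost))])
        if not failed:
            return np.array(coords)
    raise SyntheticError(
        f"contact walk failed for n={n}; try a different size or seed"
    )


def make_toy_complex(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> tuple[Structure, Structure, Assembly]:
    """Build (receptor, mobile, true assembly) with a dockable known pose.

    The true assembly has no inter-domain Cα pair closer than 4 Å and at
    least 30 pairs within 12 Å (a packed, dockable interface); the mobile
    structure is returned in its own randomly oriented local frame, with
    the ground-truth transform carried by the assembly.
    """
    from scipy.spatial.transform import Rotation

    rng = rng if rng is not None else scenario.streams()["structure"]
    rec_coords = _compact_walk(scenario.receptor_size, rng)
    rec_coords -= rec_coords.mean(axis=0)

    for _ in range(40):
        mob_global = _contact_walk(scenario.mobile_size, rec_coords, rng)
        dmat = np.linalg.norm(rec_coords[:, None, :] - mob_global[None, :, :], axis=2)
        if dmat.min() >= _MIN_SEP and np.sum(dmat < 12.0) >= 30:
            break
    else:
        raise SyntheticError("could not find a dockable pose; try another seed or sizes")

    # hide the true pose behind a random rigid transform of the local frame
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    R = Rotation.from_quat(q).as_matrix()
    t = rng.normal(0.0, 20.0, size=3)
    transform = RigidTransform(R, t)
    mob_local = transform.inverse().apply(mob_global)

    receptor = _ca_structure(rec_coords, "receptor", CHAIN_MAP["REC"])
    mobile = _ca_structure(mob_local, "mobile", CHAIN_MAP["MOB"])
    assembly = Assembly(
        [
            AssemblyComponent("REC", receptor, RigidTransform.identity(), "receptor"),
            AssemblyComponent("MOB", mobile, transform, "mobile"),
        ]
    )
    return receptor, mobile, assembly


# ---------------------------------------------------------------------------
# Cross-links

def simulate_crosslinks(
    assembly: Assembly,
    n_links: int,
    chemistry: str = "BS3",
    decoy_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    duplicate_fraction: float = 0.3,
) -> list[CrosslinkCSM]:
    """Draw cross-links from the true pose with a controlled decoy fraction.

    True links come from inter-domain pairs within the chemistry's upper
    bound, sampled with weights following the cross-linker distance
    preference (Gaussian around the chemistry target, so simulated Cα–Cα
    distances have a mean near 11.4 Å for BS3); decoys from pairs at least
    20 Å beyond the bound (flagged ``decoy`` for the evaluator only). A
    fraction of links is duplicated to emulate multiple CSMs per unique
    link. Scores follow N(9, 2) truncated at 3.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = DEFAULT_CHEMISTRY[chemistry]
    upper = params.upper_bound
    rec = assembly["REC"]
    mob = assembly["MOB"]
    rec_xyz = rec.transform.apply(rec.structure.ca_coords())
    mob_xyz = mob.transform.apply(mob.structure.ca_coords())
    dmat = np.linalg.norm(rec_xyz[:, None, :] - mob_xyz[None, :, :], axis=2)

    true_pairs = np.argwhere(dmat <= upper)
    decoy_pairs = np.argwhere(dmat > upper + 20.0)
    n_decoys = round(decoy_fraction * n_links)
    n_true = n_links - n_decoys
    if len(true_pairs) < n_true or len(decoy_pairs) < n_decoys:
        raise SyntheticError("not enough eligible residue pairs for the requested links")

    def draw_score() -> float:
        while True:
            s = rng.normal(9.0, 2.0)
            if s >= 3.0:
                return float(s)

    def make_csm(pair: np.ndarray, decoy: bool) -> CrosslinkCSM:
        i, j = int(pair[0]), int(pair[1])
        return CrosslinkCSM(
            protein_a="REC",
            residue_a=("K", i + 1),
            protein_b="MOB",
            residue_b=("K", j + 1),
            score=draw_score(),
            chemistry=chemistry,
            decoy=decoy,
        )

    # importance-weight so sampled link distances follow the chemistry's
    # distance preference (≈ N(target, 3²) truncated at the bound) instead of
    # the r²-growing pair density
    true_d = dmat[true_pairs[:, 0], true_pairs[:, 1]]
    bins = np.arange(0.0, upper + 2.0, 2.0)
    density = np.histogram(true_d, bins=bins)[0][np.digitize(true_d, bins) - 1]
    pref = np.exp(-0.5 * ((true_d - 0.92 * params.target) / 1.5) ** 2) / np.maximum(density, 1)
    pref += 1e-12
    chosen_true = true_pairs[
        rng.choice(len(true_pairs), size=n_true, replace=False, p=pref / pref.sum())
    ]
    chosen_decoy = (
        decoy_pairs[rng.choice(len(decoy_pairs), size=n_decoys, replace=False)]
        if n_decoys
        else np.zeros((0, 2), dtype=int)
    )
    csms: list[CrosslinkCSM] = []
    for pair in chosen_true:
        csms.append(make_csm(pair, decoy=False))
        if rng.random() < duplicate_fraction:
            for _ in range(int(rng.integers(1, 3))):
                csms.append(make_csm(pair, decoy=False))
    for pair in chosen_decoy:
        csms.append(make_csm(pair, decoy=True))
    return csms


# ---------------------------------------------------------------------------
# SAXS

def simulate_saxs(
    assembly: Assembly,
    s_grid: np.ndarray,
    noise_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SAXSCurve:
    """Debye profile of all Cα beads plus multiplicative Gaussian noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = np.vstack([s.ca_coords() for _, s in assembly.transformed_structures()])
    clean = debye_profile(coords, np.asarray(s_grid, dtype=float))
    if noise_fraction == 0.0:
        return clean
    sigma = noise_fraction * clean.intensity
    noisy = clean.intensity + sigma * rng.standard_normal(len(sigma))
    return SAXSCurve(s=clean.s, intensity=noisy, sigma=sigma)


# ---------------------------------------------------------------------------
# HDX

def simulate_hdx(
    assembly: Assembly,
    interface_residues: dict[str, set[int]],
    effect: float = -15.0,
    peptide_length_range: tuple[int, int] = (5, 13),
    coverage: int = 2,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 2.0,
) -> list[HDXPeptide]:
    """Tile each protein with overlapping peptides and inject protection.

    Peptides overlapping the interface receive Δ%D = effect + noise; others
    pure noise. The two timepoints share correlated noise (ρ = 0.8). Each
    full tiling pass covers every residue, so ``coverage`` passes give at
    least that much per-residue coverage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = peptide_length_range
    peptides: list[HDXPeptide] = []
    for comp in assembly.components:
        label = comp.label
        iface = interface_residues.get(label, set())
        for residues in comp.structure.chains.values():
            n = len(residues)
            numbers = [r.number for r in residues]
            for _pass in range(coverage):
                pos = 0
                while pos < n:
                    length = int(rng.integers(lo, hi + 1))
                    end = min(pos + length, n)
                    start_num, end_num = numbers[pos], numbers[end - 1]
                    overlaps = any(r in iface for r in range(start_num, end_num + 1))
                    base = effect if overlaps else 0.0
                    z1, z2 = rng.standard_normal(2)
                    noise15 = noise_sd * z1
                    noise120 = noise_sd * (0.8 * z1 + np.sqrt(1 - 0.8**2) * z2)
                    peptides.append(
                        HDXPeptide(
                            protein=label,
                            start=start_num,
                            end=end_num,
                            sequence="A" * (end_num - start_num + 1),
                            delta_15s=base + noise15,
                            delta_120s=base + noise120,
                        )
                    )
                    pos = end
    return peptides


# ---------------------------------------------------------------------------
# Interface ground truth

def true_interface_residues(assembly: Assembly, cutoff: float = 12.0) -> dict[str, set[int]]:
    """Residues of each component within ``cutoff`` Å of the other component."""
    rec = assembly["REC"]
    mob = assembly["MOB"]
    rec_xyz = rec.transform.apply(rec.structure.ca_coords())
    mob_xyz = mob.transform.apply(mob.structure.ca_coords())
    dmat = np.linalg.norm(rec_xyz[:, None, :] - mob_xyz[None, :, :], axis=2)
    rec_iface = {int(i) + 1 for i in np.where(dmat.min(axis=1) <= cutoff)[0]}
    mob_iface = {int(j) + 1 for j in np.where(dmat.min(axis=0) <= cutoff)[0]}
    return {"REC": rec_iface, "MOB": mob_iface}
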