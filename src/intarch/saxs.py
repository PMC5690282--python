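"""Small-angle scattering curve analysis.

Debye theoretical profiles from coordinates, Guinier fitting, regularized
P(r) inversion, Porod volume/mass estimation and χ² model-vs-curve fits.
The momentum transfer convention is s = 4π sinθ/λ in Å⁻¹ throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "SAXSCurve",
    "GuinierResult",
    "PrCurve",
    "PorodResult",
    "SAXSError",
    "debye_profile",
    "guinier_fit",
    "pr_transform",
    "porod_mass",
    "chi_square",
    "read_dat",
    "write_dat",
]


class SAXSError(ValueError):
    pass


@dataclass
class SAXSCurve:
    """Intensity versus momentum transfer, with optional uncertainties."""

    s: np.ndarray  # Å⁻¹, strictly increasing
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.intensity.shape:
            raise SAXSError("s and intensity must be 1-D arrays of equal length")
        if np.any(self.s < 0) or np.any(np.diff(self.s) <= 0):
            raise SAXSError("s must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SAXSError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.s.shape or np.any(self.sigma <= 0):
                raise SAXSError("sigma must be positive and match the s grid")

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class GuinierResult:
    Rg: float  # Å
    I0: float
    s_min: float
    s_max: float
    sRg_max: float
    residual: float  # RMS of ln I residuals within the fit window
    n_points: int


@dataclass
class PrCurve:
    r: np.ndarray  # Å, 0..Dmax
    p: np.ndarray
    dmax: float
    rg: float  # real-space Rg
    i0: float
    alpha: float
    residual: float  # mean squared weighted curve misfit


@dataclass
class PorodResult:
    porod_volume: float  # Å³
    molecular_mass: float  # kDa
    conversion: float  # Å³ per kDa


# ---------------------------------------------------------------------------
# Theoretical profile

#: Electron counts of amino-acid residues (chain form), used as dummy
#: scatterer weights for one-bead-per-residue Debye profiles.
RESIDUE_ELECTRONS: dict[str, float] = {
    "GLY": 30, "ALA": 38, "SER": 46, "PRO": 52, "VAL": 54, "THR": 54,
    "CYS": 54, "LEU": 62, "ILE": 62, "ASN": 60, "ASP": 59, "GLN": 68,
    "LYS": 71, "GLU": 67, "MET": 70, "HIS": 72, "PHE": 78, "ARG": 85,
    "TYR": 86, "TRP": 98,
}

def debye_profile(
    coords: np.ndarray, s_grid: np.ndarray, weights: np.ndarray | None = None
) -> SAXSCurve:
    """Coarse-grained Debye sum I(s) = Σᵢ Σⱼ fᵢ fⱼ sin(s·rᵢⱼ)/(s·rᵢⱼ).

    The sinc term is taken as 1 at s·r = 0, so I(0) = (Σf)².
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.size == 0:
        raise SAXSError("debye_profile: empty coordinate set")
    s = np.asarray(s_grid, dtype=float)
    n = len(coords)
    f = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if f.shape != (n,):
        raise SAXSError("weights must match coordinates")
    from scipy.spatial.distance import pdist

    intensity = np.full(len(s), np.sum(f**2))
    if n > 1:
        d = pdist(coords)
        iu, ju = np.triu_indices(n, k=1)
        ff = f[iu] * f[ju]
        # sinc in numpy is sin(pi x)/(pi x); evaluate in chunks to bound memory
        chunk = max(1, int(2e7) // max(len(d), 1))
        for lo in range(0, len(s), chunk):
            sl = s[lo : lo + chunk]
            arg = np.outer(sl, d)
            intensity[lo : lo + chunk] += 2.0 * (np.sinc(arg / np.pi) @ ff)
    return SAXSCurve(s=s, intensity=intensity)


def profile_from_structure(obj, s_grid: np.ndarray) -> SAXSCurve:
    """One-bead-per-residue Debye profile of a Structure or Assembly.

    Bead weights are residue electron counts; residues outside the table
    (e.g. synthetic placeholders) fall back to the ALA value.
    """
    structure = obj.flatten() if hasattr(obj, "flatten") else obj
    coords, weights = [], []
    for residues in structure.chains.values():
        for res in residues:
            for a in res.atoms:
                if a.name == "CA":
                    coords.append(a.coord)
                    weights.append(RESIDUE_ELECTRONS.get(res.name, RESIDUE_ELECTRONS["ALA"]))
                    break
    if not coords:
        raise SAXSError("no Cα beads found")
    return debye_profile(np.array(coords), s_grid, np.array(weights, dtype=float))


# ---------------------------------------------------------------------------
# Guinier

def guinier_fit(curve: SAXSCurve, sRg_limit: float = 1.3, max_iter: int = 20) -> GuinierResult:
    """Linear fit of ln I versus s² over the longest low-s window with s·Rg ≤ limit.

    The window is chosen self-consistently: starting from the first 10 points,
    the fitted Rg defines a new window, iterated to convergence.
    """
    s, I = curve.s, curve.intensity
    if len(s) < 10:
        raise SAXSError("guinier_fit: need at least 10 points")
    n_win = 10
    rg = None
    for _ in range(max_iter):
        window = slice(0, n_win)
        if np.any(I[window] <= 0):
            raise SAXSError("guinier_fit: non-positive intensities in the fit window")
        coeff = np.polyfit(s[window] ** 2, np.log(I[window]), 1)
        slope, intercept = coeff
        if slope >= 0:
            raise SAXSError("guinier_fit: non-decreasing low-s intensity, no Guinier region")
        rg = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(s, sRg_limit / rg, side="right"))
        n_new = max(n_new, 10)
        n_new = min(n_new, len(s))
        if n_new == n_win:
            break
        n_win = n_new
    window = slice(0, n_win)
    if np.any(I[window] <= 0):
        raise SAXSError("guinier_fit: non-positive intensities in the fit window")
    slope, intercept = np.polyfit(s[window] ** 2, np.log(I[window]), 1)
    if slope >= 0:
        raise SAXSError("guinier_fit: no convergent Guinier window")
    rg = float(np.sqrt(-3.0 * slope))
    pred = intercept + slope * s[window] ** 2
    residual = float(np.sqrt(np.mean((np.log(I[window]) - pred) ** 2)))
    return GuinierResult(
        Rg=rg,
        I0=float(np.exp(intercept)),
        s_min=float(s[0]),
        s_max=float(s[n_win - 1]),
        sRg_max=float(s[n_win - 1] * rg),
        residual=residual,
        n_points=n_win,
    )


# ---------------------------------------------------------------------------
# P(r) inversion

def _pr_design_matrix(s: np.ndarray, r: np.ndarray) -> np.ndarray:
    """I(s) = 4π ∫ p(r) sinc(s r) dr discretized with trapezoid weights."""
    dr = r[1] - r[0]
    w = np.full(len(r), dr)
    w[0] = w[-1] = dr / 2.0
    arg = np.outer(s, r)
    return 4.0 * np.pi * np.sinc(arg / np.pi) * w


def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def pr_transform(
    curve: SAXSCurve,
    dmax: float,
    n_r: int = 101,
    alpha: float | None = None,
) -> PrCurve:
    """Regularized indirect Fourier transform of a scattering curve.

    Solves for p(r) ≥ 0 on [0, Dmax] with p(0) = p(Dmax) = 0, minimizing
    ‖(I_model − I)/σ‖² + α‖p″‖². When ``alpha`` is None it is chosen by an
    L-curve corner scan over a 13-point log grid from 1e-4 to 1e2.
    """
    if dmax <= 0:
        raise SAXSError("pr_transform: Dmax must be positive")
    s, I = curve.s, curve.intensity
    sigma = curve.sigma if curve.sigma is not None else np.full_like(I, max(np.max(np.abs(I)), 1.0) * 1e-3)
    r = np.linspace(0.0, dmax, n_r)
    A_full = _pr_design_matrix(s, r)
    # boundary condition: drop the endpoint basis functions (p fixed to 0)
    A = A_full[:, 1:-1] / sigma[:, None]
    b = I / sigma
    L = _second_difference(n_r)[:, 1:-1]
    scale = np.linalg.norm(A.T @ A) / max(np.linalg.norm(L.T @ L), 1e-30)

    def solve(a: float) -> tuple[np.ndarray, float, float]:
        stacked = np.vstack([A, np.sqrt(a * scale) * L])
        rhs = np.concatenate([b, np.zeros(L.shape[0])])
        try:
            p_int, _ = nnls(stacked, rhs, maxiter=10 * stacked.shape[1])
        except Exception as exc:
            raise SAXSError(
                f"pr_transform: ill-conditioned system at alpha={a:g}; "
                "try alpha in [1e-4, 1e2]"
            ) from exc
        misfit = float(np.sum((A @ p_int - b) ** 2))
        rough = float(np.sum((L @ p_int) ** 2))
        return p_int, misfit, rough

    if alpha is None:
        grid = np.logspace(-4, 2, 13)
        sols = [solve(a) for a in grid]
        # L-curve corner: maximum curvature of (log misfit, log roughness)
        x = np.log10([max(m, 1e-300) for _, m, _ in sols])
        y = np.log10([max(rg, 1e-300) for _, _, rg in sols])
        best_i, best_curv = len(grid) // 2, -np.inf
        for i in range(1, len(grid) - 1):
            v1 = np.array([x[i] - x[i - 1], y[i] - y[i - 1]])
            v2 = np.array([x[i + 1] - x[i], y[i + 1] - y[i]])
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-12 or n2 < 1e-12:
                continue
            curv = v1[0] * v2[1] - v1[1] * v2[0]  # signed turn toward the corner
            if curv / (n1 * n2) > best_curv:
                best_curv = curv / (n1 * n2)
                best_i = i
        alpha = float(grid[best_i])
        p_int, misfit, _ = sols[best_i]
    else:
        p_int, misfit, _ = solve(alpha)

    p = np.zeros(n_r)
    p[1:-1] = p_int
    integral = np.trapezoid(p, r)
    if integral <= 0:
        raise SAXSError("pr_transform: degenerate solution (∫p dr ≤ 0); check Dmax/alpha")
    rg = float(np.sqrt(np.trapezoid(r**2 * p, r) / (2.0 * integral)))
    i0 = float(4.0 * np.pi * integral)
    return PrCurve(
        r=r, p=p, dmax=float(dmax), rg=rg, i0=i0, alpha=float(alpha),
        residual=misfit / len(s),
    )


# ---------------------------------------------------------------------------
# Porod

def porod_mass(
    curve_or_volume: SAXSCurve | float,
    conversion: float = 1.7e3,
) -> PorodResult:
    """Molecular mass from the Porod volume.

    Given a volume in Å³ the mass is volume / conversion. Given a curve, the
    volume is V = 2π² I(0) / Q with the Porod invariant Q = ∫ s² (I − B) ds,
    where B is a constant background estimated from the high-s tail and I(0)
    comes from a Guinier fit.
    """
    if isinstance(curve_or_volume, (int, float)):
        volume = float(curve_or_volume)
        if volume <= 0:
            raise SAXSError("porod volume must be positive")
    else:
        curve = curve_or_volume
        i0 = guinier_fit(curve).I0
        n_tail = max(3, len(curve) // 20)
        background = float(np.mean(curve.intensity[-n_tail:]))
        corrected = curve.intensity - background
        q = float(np.trapezoid(curve.s**2 * corrected, curve.s))
        if q <= 0:
            raise SAXSError("porod_mass: non-positive invariant after background subtraction")
        volume = 2.0 * np.pi**2 * i0 / q
    return PorodResult(
        porod_volume=volume,
        molecular_mass=volume / conversion,
        conversion=conversion,
    )


# ---------------------------------------------------------------------------
# χ² fit

def chi_square(model_curve: SAXSCurve, experimental: SAXSCurve) -> float:
    """Reduced χ² between a model and an experimental curve.

    The model is linearly interpolated onto the experimental grid and scaled
    by the closed-form factor minimizing χ².
    """
    s_exp = experimental.s
    I_exp = experimental.intensity
    I_mod = np.interp(s_exp, model_curve.s, model_curve.intensity)
    if experimental.sigma is None:
        warnings.warn("chi_square: experimental curve has no σ column; using unit weights")
        sigma = np.ones_like(I_exp)
    else:
        sigma = experimental.sigma
    w = 1.0 / sigma**2
    denom = np.sum(w * I_mod**2)
    if denom <= 0:
        raise SAXSError("chi_square: degenerate model curve")
    c = np.sum(w * I_mod * I_exp) / denom
    n = len(s_exp)
    if n < 2:
        raise SAXSError("chi_square: need at least 2 points")
    return float(np.sum(w * (c * I_mod - I_exp) ** 2) / (n - 1))


# ---------------------------------------------------------------------------
# I/O

def read_dat(path: str | Path) -> SAXSCurve:
    """Read a 3-column whitespace-delimited (s, I[, σ]) curve; '#' comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise SAXSError(f"{path}: expected at least 2 columns (s, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(s=data[:, 0], intensity=data[:, 1], sigma=sigma)


def write_dat(curve: SAXSCurve, path: str | Path, header: str = "") -> None:
    cols = [curve.s, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header=header, comments="# ")
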