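"""Package-wide configurable defaults.

Values users most often need to override (chemistry distance parameters,
chain maps, residue-number offsets) are plain data here so they can be
echoed into run reports.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ChemistryParams:
    """Distance restraint parameters for one cross-linking chemistry."""

    target: float  # Å, zero-penalty radius / refinement target
    upper_bound: float  # Å, satisfaction cutoff


#: BS3 target is the refinement mean of the lysine-lysine spacer chemistry;
#: the 30 Å satisfaction cutoff is the community-standard Cα–Cα allowance
#: (spacer plus two side chains). Photo chemistry is near-zero-length.
DEFAULT_CHEMISTRY: dict[str, ChemistryParams] = {
    "BS3": ChemistryParams(target=11.4, upper_bound=30.0),
    "photo": ChemistryParams(target=5.0, upper_bound=15.0),
}

DEFAULTS: dict[str, object] = {
    "clms.weighting": "uniform",  # or "score"
    "docking.clash_distance": 4.0,  # Å, Cα–Cα soft-core radius
    "docking.satisfaction_threshold": 0.90,
    "docking.n_starts": 512,
    "docking.seed": 2017,
    "hdx.significance_threshold": 7.0,  # percentage points |Δ%D|
    "hdx.trim_n_residues": 0,
    "saxs.sRg_limit": 1.3,
    "saxs.porod_conversion": 1.7e3,  # Å³ per kDa
    "sasa.probe_radius": 1.4,  # Å
    "sasa.n_points": 960,
    "sasa.ca_only_radius": 3.0,  # Å, inflated radius for Cα-only models
}
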