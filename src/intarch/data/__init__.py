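"""Bundled plain-text fixtures: printed cross-link and HDX deuteration tables."""

from importlib import resources

__all__ = ["bs3_crosslink_text", "hdx_deuteration_text"]


def _read(name: str) -> str:
    return resources.files(__package__).joinpath(name).read_text(encoding="utf-8")


def bs3_crosslink_text() -> str:
    """The three-block BS3 cross-link table (paper_table dialect)."""
    return _read("bs3_crosslinks.tsv")


def hdx_deuteration_text() -> str:
    """The per-protein HDX Δ%D peptide table (paper_table dialect)."""
    return _read("hdx_deuteration.tsv")
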