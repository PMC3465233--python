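"""A tiny worked example: the heat-shock / proteasome regulatory chain.

Hsf1 binds the *HSP82* promoter directly, reaches *RPT4* only through the
intermediate TF Rpn4 (Hsf1 -> RPN4 -> RPT4, a literature-validated chain),
and has no path at all to *YGR259C*; Stp2 reaches *ETR1* through Adr1.
Useful for demos, docs and tests.
"""

from __future__ import annotations

from .network import EdgeRecord, RegulatoryNetwork, SupportMode, build_network

__all__ = ["example_edges", "example_network", "example_targets"]


def example_edges() -> list[EdgeRecord]:
    return [
        EdgeRecord("HSF1", "HSP82", binding=True, regulation=True),
        EdgeRecord("HSF1", "RPN4", binding=True, regulation=True),
        EdgeRecord("RPN4", "RPT4", binding=True, regulation=True),
        EdgeRecord("STP2", "ADR1", binding=True, regulation=True),
        EdgeRecord("ADR1", "ETR1", binding=True, regulation=False),
    ]


def example_network(mode: SupportMode = SupportMode.BINDING) -> RegulatoryNetwork:
    return build_network(example_edges(), mode)


def example_targets() -> dict[str, list[str]]:
    """Knockout-target lists exercising all three outcomes."""
    return {"HSF1": ["HSP82", "RPT4", "YGR259C"], "STP2": ["ETR1"]}
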