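"""End-to-end scoring: weighting -> MPR -> IPCC -> SCP fusion in one call."""

from __future__ import annotations

from typing import Dict, Optional

from .correlation import compute_ipcc
from .datatypes import (CompartmentAnnotation, ExpressionMatrix, PPINetwork,
                        ScoreVector)
from .fusion import scp_score
from .pagerank import build_transition_model, mpr
from .weighting import compute_ipsc, weight_network

__all__ = ["score_proteins"]


def score_proteins(
    network: PPINetwork,
    annotation: CompartmentAnnotation,
    expression: Optional[ExpressionMatrix],
    lam: float = 0.5,
    alpha: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
    orientation: str = "row",
    norm: str = "l1",
    ipcc_mode: str = "signed",
    fallback_weight: Optional[float] = None,
) -> Dict[str, ScoreVector]:
    """Run the full pipeline; returns {"MPR": ..., "IPCC": ..., "SCP": ...}.

    ``expression`` may be None only when ``lam == 1`` (the co-expression
    channel is then unused and IPCC is omitted from the result).
    """
    weighted = weight_network(network, annotation, fallback=fallback_weight)
    ipsc = compute_ipsc(weighted)
    model = build_transition_model(weighted, ipsc, alpha=alpha,
                                   orientation=orientation)
    mpr_scores = mpr(model, tol=tol, max_iter=max_iter, norm=norm)
    out: Dict[str, ScoreVector] = {"MPR": mpr_scores}
    if expression is None:
        if lam != 1.0:
            raise ValueError("expression data is required unless lambda == 1")
        from .fusion import nis
        scp = nis(mpr_scores)
        scp.name = "SCP"
        out["SCP"] = scp
        return out
    ipcc = compute_ipcc(network, expression, mode=ipcc_mode)
    out["IPCC"] = ipcc
    out["SCP"] = scp_score(mpr_scores, ipcc, lam=lam)
    return out
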