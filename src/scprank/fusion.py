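"""Min–max normalization and the lambda-weighted SCP score fusion.

SCP = lambda * NIS(MPR) + (1 - lambda) * NIS(IPCC), lambda in [0, 1].

NIS rescales a score vector affinely to [0, 1] so the two channels are
commensurable before mixing; lambda = 1 reduces SCP to the network channel
(MPR) and lambda = 0 to the co-expression channel (IPCC).  Degree centrality
is included as the standard topological baseline.
"""

from __future__ import annotations

from typing import List, Tuple

from .datatypes import PPINetwork, ScoreVector

__all__ = ["nis", "scp_score", "rank", "degree_centrality"]


def nis(scores: ScoreVector) -> ScoreVector:
    """Min–max normalize to [0, 1]; a constant vector maps to all zeros."""
    if len(scores) == 0:
        raise ValueError("cannot normalize an empty score vector")
    values = scores.scores.values()
    lo, hi = min(values), max(values)
    if hi == lo:
        normed = {p: 0.0 for p in scores.scores}
    else:
        span = hi - lo
        normed = {p: (s - lo) / span for p, s in scores.items()}
    return ScoreVector(normed, name=f"NIS({scores.name})")


def scp_score(mpr_scores: ScoreVector, ipcc_scores: ScoreVector,
              lam: float = 0.5) -> ScoreVector:
    """Convex combination of the two normalized channels.

    Both inputs must score exactly the same protein set.  The inputs are
    normalized internally, so raw MPR and IPCC vectors can be passed directly.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if mpr_scores.ids != ipcc_scores.ids:
        diff = sorted(mpr_scores.ids ^ ipcc_scores.ids)[:10]
        raise ValueError(f"score vectors cover different proteins; first "
                         f"mismatches: {diff}")
    a = nis(mpr_scores)
    b = nis(ipcc_scores)
    combined = {p: lam * a[p] + (1.0 - lam) * b[p] for p in a.scores}
    return ScoreVector(combined, name="SCP")


def rank(scores: ScoreVector) -> List[Tuple[int, str, float]]:
    """Descending-score ranking; ties broken by ascending protein ID."""
    if len(scores) == 0:
        raise ValueError("cannot rank an empty score vector")
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(i, p, s) for i, (p, s) in enumerate(order, start=1)]


def degree_centrality(network: PPINetwork) -> ScoreVector:
    """Node degree as a score — the simplest topological baseline."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    return ScoreVector({p: float(d) for p, d in network.graph.degree},
                       name="DC")
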