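"""Compartment-importance edge weighting and the per-protein IPSC prior.

The model assumes that an interaction carried out inside a small subcellular
compartment is more reliable evidence of functional importance than one inside
a large compartment.  Three quantities implement this:

* ISC(C) = 1 / N_C — the importance of compartment C is the reciprocal of its
  member count, so small compartments score high;
* W_PPI(P_i, P_j) — the weight of an interaction: the *maximum* ISC over the
  compartments the two proteins share, or, when they share none, the
  *minimum* ISC over the union of their compartments;
* IPSC(P_i) = sum of W_PPI over the edges incident to P_i — a prior importance
  used as the personalized reset distribution of the modified PageRank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

from .datatypes import CompartmentAnnotation, PPINetwork, ScoreVector

logger = logging.getLogger(__name__)

__all__ = ["ISCTable", "compute_isc", "edge_weight", "weight_network",
           "compute_ipsc"]


@dataclass
class ISCTable:
    """Compartment ID -> importance score, exact reciprocal of its size."""

    isc: Dict[str, float]

    def __getitem__(self, comp: str) -> float:
        return self.isc[comp]

    @property
    def min_value(self) -> float:
        """Importance of the largest compartment (smallest ISC)."""
        return min(self.isc.values())


def compute_isc(annotation: CompartmentAnnotation) -> ISCTable:
    """ISC(C) = 1/N_C for every compartment in the annotation."""
    if not annotation.sizes:
        raise ValueError("annotation has no compartments")
    for comp, size in annotation.sizes.items():
        if size < 1:
            raise ValueError(f"compartment {comp!r} has non-positive size {size}")
    return ISCTable({c: 1.0 / n for c, n in annotation.sizes.items()})


def edge_weight(p_i: str, p_j: str, annotation: CompartmentAnnotation,
                isc: ISCTable, fallback: Optional[float] = None) -> float:
    """Co-localization weight of a single interaction.

    Intersection branch: max ISC over shared compartments.  Otherwise: min ISC
    over the union of the two compartment sets (when exactly one endpoint is
    annotated the union is just its set, no special case).  When both
    endpoints are unannotated the configured ``fallback`` applies; by default
    that is the minimum ISC in the table, treating the pair as no more
    reliable than the largest compartment.
    """
    scl_i = annotation.scl_of(p_i)
    scl_j = annotation.scl_of(p_j)
    shared = scl_i & scl_j
    if shared:
        return max(isc[c] for c in shared)
    union = scl_i | scl_j
    if union:
        return min(isc[c] for c in union)
    return fallback if fallback is not None else isc.min_value


def weight_network(network: PPINetwork, annotation: CompartmentAnnotation,
                   fallback: Optional[float] = None) -> PPINetwork:
    """Attach a co-localization weight to every edge of the network.

    Node and edge sets are unchanged; all weights are replaced atomically.
    Unannotated-unannotated pairs get the fallback weight, logged once.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot weight an empty network")
    isc = compute_isc(annotation)
    fb = fallback if fallback is not None else isc.min_value
    n_fallback = 0
    weights = {}
    for u, v in network.graph.edges:
        if not (annotation.scl_of(u) | annotation.scl_of(v)):
            n_fallback += 1
            weights[(u, v)] = fb
        else:
            weights[(u, v)] = edge_weight(u, v, annotation, isc)
    for (u, v), w in weights.items():
        network.graph.edges[u, v]["weight"] = w
    if n_fallback:
        logger.info("applied fallback weight %.6g to %d edge(s) with no "
                    "annotation on either endpoint", fb, n_fallback)
    return network


def compute_ipsc(network: PPINetwork) -> ScoreVector:
    """IPSC(P) = sum of the weights of the edges incident to P (0 if isolated)."""
    if not network.is_weighted:
        raise ValueError("network edges carry no weights; run weight_network first")
    ipsc = {p: 0.0 for p in network.graph.nodes}
    for u, v, d in network.graph.edges(data=True):
        w = float(d["weight"])
        ipsc[u] += w
        ipsc[v] += w
    return ScoreVector(ipsc, name="IPSC")
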