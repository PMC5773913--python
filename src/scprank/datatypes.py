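"""Core domain containers shared by every module.

The containers are deliberately thin: the PPI network wraps a
:class:`networkx.Graph`, expression profiles are plain numpy vectors keyed by
protein ID, and score vectors are ID->float maps with a provenance label.
All IDs are strings, stripped of surrounding whitespace at load time; matching
across the four input kinds is exact string equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "PPINetwork",
    "CompartmentAnnotation",
    "ExpressionMatrix",
    "EssentialSet",
    "ScoreVector",
    "RankVector",
    "BinaryCurve",
    "LinkProportionRow",
]


@dataclass
class PPINetwork:
    """Undirected simple PPI graph over protein IDs.

    Self-loops are forbidden and each unordered pair appears at most once
    (both enforced by the constructors in :mod:`scprank.io_formats`).  Edge
    weights are absent until :func:`scprank.weighting.weight_network` attaches
    them; ``is_weighted`` reports whether every edge carries one.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str]],
                   extra_nodes: Iterable[str] = ()) -> "PPINetwork":
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for u, v in edges:
            if u == v:
                continue
            g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> FrozenSet[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> FrozenSet[FrozenSet[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_weighted(self) -> bool:
        if self.n_edges == 0:
            return False
        return all("weight" in d for _, _, d in self.graph.edges(data=True))

    def weight(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["weight"])

    def degree(self, u: str) -> int:
        return int(self.graph.degree[u])

    def neighbors(self, u: str) -> List[str]:
        return list(self.graph.neighbors(u))

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("PPI network contains a self-loop")
        for u, v, d in self.graph.edges(data=True):
            if "weight" in d and not d["weight"] > 0:
                raise ValueError(f"non-positive weight on edge ({u}, {v})")


@dataclass
class CompartmentAnnotation:
    """Protein -> set of compartment IDs, plus per-compartment member counts.

    ``sizes[C]`` is the number of proteins annotated to compartment ``C``
    (N_C); when computed from the annotation itself it equals the count of
    distinct annotated proteins mapping to ``C``.
    """

    scl: Dict[str, FrozenSet[str]]
    sizes: Dict[str, int]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "CompartmentAnnotation":
        scl: Dict[str, set] = {}
        for protein, comp in pairs:
            scl.setdefault(protein, set()).add(comp)
        sizes: Dict[str, int] = {}
        for comps in scl.values():
            for c in comps:
                sizes[c] = sizes.get(c, 0) + 1
        return cls({p: frozenset(s) for p, s in scl.items()}, sizes)

    def scl_of(self, protein: str) -> FrozenSet[str]:
        """Compartment set of ``protein``; empty if unannotated."""
        return self.scl.get(protein, frozenset())

    def validate(self) -> None:
        counts: Dict[str, int] = {}
        for comps in self.scl.values():
            for c in comps:
                counts[c] = counts.get(c, 0) + 1
        for c, n in counts.items():
            if c not in self.sizes:
                raise ValueError(f"compartment {c!r} annotated but has no size")
            if self.sizes[c] < max(1, n):
                raise ValueError(
                    f"size of compartment {c!r} ({self.sizes[c]}) is below its "
                    f"annotated member count ({n})")


@dataclass
class ExpressionMatrix:
    """One numeric profile of length ``m`` per protein (m time points)."""

    profiles: Dict[str, np.ndarray]
    m: int

    @classmethod
    def from_dict(cls, profiles: Mapping[str, Iterable[float]]) -> "ExpressionMatrix":
        arrs = {p: np.asarray(v, dtype=float) for p, v in profiles.items()}
        lengths = {a.size for a in arrs.values()}
        if len(lengths) > 1:
            raise ValueError(f"profiles have unequal lengths: {sorted(lengths)}")
        m = lengths.pop() if lengths else 0
        if arrs and m < 2:
            raise ValueError("profiles must have at least 2 time points")
        return cls(arrs, m)

    def profile(self, protein: str) -> Optional[np.ndarray]:
        return self.profiles.get(protein)

    def __contains__(self, protein: str) -> bool:
        return protein in self.profiles

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class EssentialSet:
    """Reference set of proteins labelled essential (the positive class)."""

    ids: FrozenSet[str]

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "EssentialSet":
        return cls(frozenset(ids))

    def restricted_to(self, universe: Iterable[str]) -> "EssentialSet":
        return EssentialSet(self.ids & frozenset(universe))

    def __contains__(self, protein: str) -> bool:
        return protein in self.ids

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ScoreVector:
    """Protein -> real importance score with a provenance label.

    Ranking order is descending score, ties broken by ascending protein ID,
    which makes every downstream ranking deterministic.
    """

    scores: Dict[str, float]
    name: str = "custom"

    @property
    def ids(self) -> FrozenSet[str]:
        return frozenset(self.scores)

    def __getitem__(self, protein: str) -> float:
        return self.scores[protein]

    def __len__(self) -> int:
        return len(self.scores)

    def items(self):
        return self.scores.items()


@dataclass
class RankVector(ScoreVector):
    """ScoreVector with power-iteration diagnostics attached."""

    iterations_used: int = 0
    converged: bool = False
    residual: float = float("nan")


@dataclass
class BinaryCurve:
    """An evaluation curve (ROC, PR or jackknife) with its trapezoidal area."""

    x: np.ndarray
    y: np.ndarray
    auc: float
    kind: str  # "roc" | "pr" | "jackknife"

    @property
    def points(self) -> List[Tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))


@dataclass
class LinkProportionRow:
    """Edge-class fractions of the subgraph induced by the top-k proteins."""

    top_k: int
    ess_ess: float
    ess_noness: float
    noness_noness: float
    n_edges: int = 0

    @property
    def has_edges(self) -> bool:
        return self.n_edges > 0
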