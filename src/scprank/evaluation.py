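"""Ranking evaluation: ROC/AUC, precision–recall, jackknife curves, top-percent
essential counts and link-proportion analysis of top-ranked subnetworks.

All metrics sweep the deterministic ranking (descending score, protein-ID
tie-break) cutoff by cutoff: the top-k proteins are predicted essential, the
rest non-essential.  The reference essential set is restricted to proteins
present in the scored set before any count is taken.  An optional
``restrict_top`` truncates the sweep at a fixed rank (the top-|essential set|
protocol); proteins beyond the truncation are treated as predicted-negative
at every threshold, so a truncated ROC ends short of (1, 1).
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (BinaryCurve, EssentialSet, LinkProportionRow,
                        PPINetwork, ScoreVector)
from .fusion import rank

__all__ = ["confusion_at_k", "roc_curve", "pr_curve", "jackknife_curve",
           "top_percent_counts", "link_proportions", "ranked_ids",
           "write_curve", "plot_curves"]


def ranked_ids(scores: ScoreVector) -> List[str]:
    """Protein IDs in ranking order."""
    return [p for _, p, _ in rank(scores)]


def confusion_at_k(ranking: Sequence[str], essential: EssentialSet,
                   k: int) -> Tuple[int, int, int, int]:
    """(TP, FP, TN, FN) when the top-k proteins are predicted essential.

    The essential set is first restricted to proteins present in the ranking.
    """
    n = len(ranking)
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range [0, {n}]")
    ess = essential.ids & frozenset(ranking)
    tp = sum(1 for p in ranking[:k] if p in ess)
    fp = k - tp
    fn = len(ess) - tp
    tn = (n - k) - fn
    return tp, fp, tn, fn


def _sweep_counts(ranking: Sequence[str], essential: EssentialSet,
                  limit: int) -> Tuple[np.ndarray, int, int]:
    """Cumulative TP over k = 0..limit, plus (n_pos, n_neg) of the full ranking."""
    ess = essential.ids & frozenset(ranking)
    n_pos = len(ess)
    n_neg = len(ranking) - n_pos
    hits = np.fromiter((1 if p in ess else 0 for p in ranking[:limit]),
                       dtype=int, count=limit)
    tp = np.concatenate(([0], np.cumsum(hits)))
    return tp, n_pos, n_neg


def _resolve_limit(n: int, restrict_top: Optional[int]) -> int:
    if restrict_top is None:
        return n
    if not 1 <= restrict_top <= n:
        raise ValueError(f"restrict_top={restrict_top} out of range [1, {n}]")
    return restrict_top


def roc_curve(scores: ScoreVector, essential: EssentialSet,
              restrict_top: Optional[int] = None) -> BinaryCurve:
    """ROC curve over the ranking sweep; AUC by the trapezoid rule.

    FPR = FP/(FP+TN) and TPR = TP/(TP+FN) are computed against the full
    scored set at every cutoff; ``restrict_top`` only truncates the sweep.
    """
    ranking = ranked_ids(scores)
    limit = _resolve_limit(len(ranking), restrict_top)
    tp, n_pos, n_neg = _sweep_counts(ranking, essential, limit)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    k = np.arange(limit + 1)
    fpr = (k - tp) / n_neg
    tpr = tp / n_pos
    auc = float(np.trapezoid(tpr, fpr))
    return BinaryCurve(fpr, tpr, auc, kind="roc")


def pr_curve(scores: ScoreVector, essential: EssentialSet,
             restrict_top: Optional[int] = None) -> BinaryCurve:
    """Precision–recall curve over the ranking sweep (k = 1..limit)."""
    ranking = ranked_ids(scores)
    limit = _resolve_limit(len(ranking), restrict_top)
    tp, n_pos, n_neg = _sweep_counts(ranking, essential, limit)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("PR needs at least one positive and one negative")
    k = np.arange(1, limit + 1)
    recall = tp[1:] / n_pos
    precision = tp[1:] / k
    auc = float(np.trapezoid(precision, recall))
    return BinaryCurve(recall, precision, auc, kind="pr")


def jackknife_curve(scores: ScoreVector, essential: EssentialSet,
                    top_n: Optional[int] = None) -> BinaryCurve:
    """Cumulative essential count versus rank position 1..top_n."""
    ranking = ranked_ids(scores)
    limit = _resolve_limit(len(ranking), top_n)
    tp, _, _ = _sweep_counts(ranking, essential, limit)
    x = np.arange(1, limit + 1, dtype=float)
    y = tp[1:].astype(float)
    auc = float(np.trapezoid(y, x))
    return BinaryCurve(x, y, auc, kind="jackknife")


def top_percent_counts(scores: ScoreVector, essential: EssentialSet,
                       percents: Iterable[float]) -> Dict[float, int]:
    """Essential count within the top p% of the ranking, per percent.

    k = round-half-up(p/100 * N).
    """
    ranking = ranked_ids(scores)
    n = len(ranking)
    out: Dict[float, int] = {}
    for p in percents:
        if not 0 < p <= 100:
            raise ValueError(f"percent {p} outside (0, 100]")
        k = int(math.floor(p / 100.0 * n + 0.5))
        tp, _, _, _ = confusion_at_k(ranking, essential, k)
        out[p] = tp
    return out


def link_proportions(network: PPINetwork, ranking: Sequence[str],
                     essential: EssentialSet, top_k: int) -> LinkProportionRow:
    """Classify the edges among the top-k proteins by endpoint essentiality.

    Uses the full network's edges restricted to the top-k node set.  With no
    induced edges the three fractions are reported as 0 and ``has_edges`` is
    False (not an error).
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    top = list(ranking[:top_k])
    sub = network.graph.subgraph(top)
    n_ee = n_en = n_nn = 0
    for u, v in sub.edges:
        ess_count = (u in essential) + (v in essential)
        if ess_count == 2:
            n_ee += 1
        elif ess_count == 1:
            n_en += 1
        else:
            n_nn += 1
    total = n_ee + n_en + n_nn
    if total == 0:
        return LinkProportionRow(top_k, 0.0, 0.0, 0.0, n_edges=0)
    return LinkProportionRow(top_k, n_ee / total, n_en / total, n_nn / total,
                             n_edges=total)


def write_curve(curve: BinaryCurve, path) -> None:
    """Export a curve as a two-column TSV (x, y per row)."""
    headers = {"roc": ("fpr", "tpr"), "pr": ("recall", "precision"),
               "jackknife": ("rank", "cumulative_essential")}
    hx, hy = headers.get(curve.kind, ("x", "y"))
    with open(path, "w") as fh:
        fh.write(f"{hx}\t{hy}\n")
        for x, y in zip(curve.x, curve.y):
            fh.write(f"{format(float(x), '.10g')}\t{format(float(y), '.10g')}\n")


def plot_curves(curves: Dict[str, BinaryCurve], path, title: str = "") -> None:
    """Render one or more same-kind curves to a static image (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    kinds = {c.kind for c in curves.values()}
    if len(kinds) != 1:
        raise ValueError("all curves in one plot must share a kind")
    kind = kinds.pop()
    labels = {"roc": ("FPR", "TPR"), "pr": ("Recall", "Precision"),
              "jackknife": ("Rank", "Cumulative essential proteins")}
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in sorted(curves.items()):
        ax.plot(c.x, c.y, label=f"{name} (AUC={c.auc:.4f})")
    xl, yl = labels[kind]
    ax.set_xlabel(xl)
    ax.set_ylabel(yl)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
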