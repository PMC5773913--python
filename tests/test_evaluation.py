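"""Confusion counts, ROC/PR/jackknife sweeps, top-percent and link analysis."""

import numpy as np
import pytest

from scprank.datatypes import EssentialSet, ScoreVector
from scprank import evaluation as ev

from conftest import make_network


def sv(ordered_ids):
    """ScoreVector whose ranking equals the given order."""
    n = len(ordered_ids)
    return ScoreVector({p: float(n - i) for i, p in enumerate(ordered_ids)})


class TestConfusion:
    def test_perfect_split(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        assert ev.confusion_at_k(["E1", "E2", "N1", "N2"], ess, 2) == (2, 0, 2, 0)

    def test_boundary_k_zero(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        assert ev.confusion_at_k(["E1", "E2", "N1", "N2"], ess, 0) == (0, 0, 2, 2)

    def test_inverted(self):
        ess = EssentialSet(frozenset({"E1"}))
        assert ev.confusion_at_k(["N1", "E1"], ess, 1) == (0, 1, 0, 1)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ev.confusion_at_k(["A"], EssentialSet(frozenset({"A"})), 2)

    def test_conservation_at_every_cutoff(self):
        rng = np.random.default_rng(0)
        ranking = [f"P{i}" for i in range(40)]
        ess = EssentialSet(frozenset(rng.choice(ranking, 12, replace=False)))
        for k in range(41):
            tp, fp, tn, fn = ev.confusion_at_k(ranking, ess, k)
            assert tp + fp == k
            assert tp + fn == 12
            assert tp + fp + tn + fn == 40

    def test_labels_outside_ranking_ignored(self):
        ess = EssentialSet(frozenset({"E1", "GHOST"}))
        tp, fp, tn, fn = ev.confusion_at_k(["E1", "N1"], ess, 2)
        assert (tp, fn) == (1, 0)


class TestROC:
    def test_perfect_and_reversed(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        assert ev.roc_curve(sv(["E1", "E2", "N1", "N2"]), ess).auc == \
            pytest.approx(1.0)
        assert ev.roc_curve(sv(["N1", "N2", "E1", "E2"]), ess).auc == \
            pytest.approx(0.0)

    def test_endpoints_of_full_sweep(self):
        ess = EssentialSet(frozenset({"E1"}))
        c = ev.roc_curve(sv(["E1", "N1", "N2"]), ess)
        assert (c.x[0], c.y[0]) == (0.0, 0.0)
        assert (c.x[-1], c.y[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.x) >= 0) and np.all(np.diff(c.y) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_curve(sv(["A", "B"]), EssentialSet(frozenset({"A", "B"})))

    def test_matches_mann_whitney_u(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 60
            scores = rng.normal(size=n)  # continuous -> no ties
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            vec = ScoreVector({f"P{i}": float(s) for i, s in enumerate(scores)})
            ess = EssentialSet(frozenset(f"P{i}" for i in np.where(labels)[0]))
            u = mannwhitneyu(scores[labels], scores[~labels],
                             alternative="two-sided").statistic
            expect = u / (labels.sum() * (~labels).sum())
            assert ev.roc_curve(vec, ess).auc == pytest.approx(expect, abs=1e-12)

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(50):
            n = 2000
            vec = ScoreVector({f"P{i}": float(s)
                               for i, s in enumerate(rng.normal(size=n))})
            ess = EssentialSet(frozenset(
                f"P{i}" for i in rng.choice(n, n // 5, replace=False)))
            aucs.append(ev.roc_curve(vec, ess).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_truncated_sweep_stops_short(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        c = ev.roc_curve(sv(["E1", "N1", "E2", "N2"]), ess, restrict_top=2)
        assert len(c.x) == 3  # k = 0, 1, 2
        assert c.x[-1] < 1.0 or c.y[-1] < 1.0


class TestPR:
    def test_perfect_ranking_all_precision_one(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        c = ev.pr_curve(sv(["E1", "E2", "N1"]), ess, restrict_top=2)
        assert np.all(c.y == 1.0)

    def test_precision_equals_tp_over_k(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        ranking = ["E1", "N1", "E2", "N2"]
        c = ev.pr_curve(sv(ranking), ess)
        for idx, k in enumerate(range(1, 5)):
            tp, _, _, _ = ev.confusion_at_k(ranking, ess, k)
            assert c.y[idx] == pytest.approx(tp / k)


class TestJackknife:
    def test_cumulative_counts(self):
        ess = EssentialSet(frozenset({"E1", "E2"}))
        c = ev.jackknife_curve(sv(["E1", "N1", "E2"]), ess, top_n=3)
        assert c.y.tolist() == [1.0, 1.0, 2.0]
        assert np.all(np.diff(c.y) >= 0)

    def test_final_count_consistent_with_confusion(self):
        rng = np.random.default_rng(5)
        ranking = [f"P{i}" for i in range(30)]
        ess = EssentialSet(frozenset(rng.choice(ranking, 9, replace=False)))
        c = ev.jackknife_curve(sv(ranking), ess, top_n=20)
        tp, _, _, _ = ev.confusion_at_k(ranking, ess, 20)
        assert c.y[-1] == tp

    def test_top_n_out_of_range(self):
        with pytest.raises(ValueError):
            ev.jackknife_curve(sv(["A", "B"]),
                               EssentialSet(frozenset({"A"})), top_n=5)


class TestTopPercent:
    def test_round_half_up(self):
        ranking = [f"P{i:03d}" for i in range(200)]
        ess = EssentialSet(frozenset(ranking[:2]))
        counts = ev.top_percent_counts(sv(ranking), ess, [1])
        assert counts[1] == 2  # k = round(0.01 * 200) = 2, both essential

    def test_perfect_ranking_recovers_all(self):
        n = 100
        ranking = [f"E{i}" for i in range(20)] + [f"N{i}" for i in range(80)]
        ess = EssentialSet(frozenset(r for r in ranking if r.startswith("E")))
        counts = ev.top_percent_counts(sv(ranking), ess, [20])
        assert counts[20] == 20

    def test_monotone_in_percent(self):
        rng = np.random.default_rng(3)
        ranking = [f"P{i}" for i in range(120)]
        ess = EssentialSet(frozenset(rng.choice(ranking, 30, replace=False)))
        counts = ev.top_percent_counts(sv(ranking), ess, [1, 5, 10, 25, 50])
        vals = [counts[p] for p in (1, 5, 10, 25, 50)]
        assert vals == sorted(vals)

    def test_invalid_percent(self):
        with pytest.raises(ValueError):
            ev.top_percent_counts(sv(["A", "B"]),
                                  EssentialSet(frozenset({"A"})), [0])


class TestLinkProportions:
    def test_all_essential_triangle(self):
        net = make_network([("E1", "E2"), ("E2", "E3"), ("E1", "E3")])
        ess = EssentialSet(frozenset({"E1", "E2", "E3"}))
        row = ev.link_proportions(net, ["E1", "E2", "E3"], ess, 3)
        assert row.ess_ess == 1.0 and row.noness_noness == 0.0

    def test_mixed_path(self):
        net = make_network([("E1", "N1"), ("N1", "E2")])
        ess = EssentialSet(frozenset({"E1", "E2"}))
        row = ev.link_proportions(net, ["E1", "N1", "E2"], ess, 3)
        assert row.ess_noness == 1.0

    def test_four_cycle_enumeration(self):
        net = make_network([("E1", "E2"), ("E2", "N1"), ("N1", "N2"),
                            ("N2", "E1")])
        ess = EssentialSet(frozenset({"E1", "E2"}))
        row = ev.link_proportions(net, ["E1", "E2", "N1", "N2"], ess, 4)
        assert row.ess_ess == pytest.approx(0.25)
        assert row.ess_noness == pytest.approx(0.5)
        assert row.noness_noness == pytest.approx(0.25)
        assert row.ess_ess + row.ess_noness + row.noness_noness == \
            pytest.approx(1.0, abs=1e-12)

    def test_no_induced_edges_flagged(self):
        net = make_network([("A", "B")], extra_nodes=["C", "D"])
        row = ev.link_proportions(net, ["C", "D"],
                                  EssentialSet(frozenset({"C"})), 2)
        assert not row.has_edges
        assert row.ess_ess == row.ess_noness == row.noness_noness == 0.0

    def test_top_k_too_small(self):
        net = make_network([("A", "B")])
        with pytest.raises(ValueError):
            ev.link_proportions(net, ["A", "B"],
                                EssentialSet(frozenset({"A"})), 1)


def test_curve_tsv_round_trip(tmp_path):
    ess = EssentialSet(frozenset({"E1"}))
    c = ev.roc_curve(sv(["E1", "N1", "N2"]), ess)
    path = tmp_path / "roc.tsv"
    ev.write_curve(c, path)
    data = np.loadtxt(path, skiprows=1)
    assert np.allclose(data[:, 0], c.x) and np.allclose(data[:, 1], c.y)
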