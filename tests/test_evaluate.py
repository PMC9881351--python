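"""ROC/AUC diagnostics and Kaplan-Meier / log-rank prognostics."""

import numpy as np
import pandas as pd
import pytest

from neuromarker import SynthConfig, gen_expression, gen_survival, km_logrank, roc_auc


def brute_force_auc(scores, labels) -> float:
    """Oracle: all case-control pairs, ties half-credited."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    wins = sum(
        1.0 if c > k else 0.5 if c == k else 0.0 for c in cases for k in controls
    )
    return wins / (len(cases) * len(controls))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_auc([3, 4, 1, 2], [True, True, False, False])
        assert res.auc == 1.0

    def test_all_ties_half(self):
        res = roc_auc([5, 5, 5, 5], [True, True, False, False])
        assert res.auc == 0.5

    def test_hand_counted_pairs(self):
        # cases {2,3}, controls {1,4}: wins (2,1) and (3,1) only -> 2/4
        res = roc_auc([2, 3, 1, 4], [True, True, False, False])
        assert res.auc == pytest.approx(brute_force_auc([2, 3, 1, 4],
                                                        [1, 1, 0, 0]))
        assert res.auc == pytest.approx(0.5)

    def test_matches_all_pairs_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.arange(10) / 3, size=n)  # frequent ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_label_swap_complements(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels).auc == pytest.approx(
            1 - roc_auc(scores, ~labels).auc
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = np.arange(30) % 3 == 0
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores), labels).auc
        assert a == pytest.approx(b)

    def test_curve_geometry_and_trapezoid(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        res = roc_auc(scores, labels)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert np.trapezoid(res.tpr, res.fpr) == pytest.approx(res.auc)

    def test_direction_flag_and_one_class_error(self):
        res = roc_auc([3, 4, 1, 2], [True, True, False, False],
                      higher_is_case=False)
        assert res.auc == 0.0
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])


def _surv(times, events, samples=None):
    samples = samples or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample": samples, "time": times, "event": events})


class TestKmLogrank:
    def test_identical_groups_null_identity(self):
        # expression splits 4 high / 4 low with identical survival per group
        expr = pd.Series([1, 1, 1, 1, 2, 2, 2, 2],
                         index=[f"s{i}" for i in range(8)])
        surv = _surv([5, 8, 12, 20] * 2, [1, 1, 0, 1] * 2)
        res = km_logrank(expr, surv)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        expr = pd.Series([1, 1, 1, 3, 3, 3], index=[f"s{i}" for i in range(6)])
        surv = _surv([2, 4, 6, 1, 3, 5], [1] * 6)
        res = km_logrank(expr, surv)
        low = res.curves["low"].set_index("time")["survival"]
        # low group times 2,4,6 -> S = 2/3, 1/3, 0 at those times
        assert low.loc[2.0] == pytest.approx(2 / 3)
        assert low.loc[4.0] == pytest.approx(1 / 3)
        assert low.loc[6.0] == pytest.approx(0.0)

    def test_stochastic_ordering_of_curves(self):
        expr = pd.Series([5, 6, 7, 8, 1, 2, 3, 4],
                         index=[f"s{i}" for i in range(8)])
        surv = _surv([1, 2, 3, 4, 10, 11, 12, 13], [1] * 8)
        res = km_logrank(expr, surv)
        high = res.curves["high"].set_index("time")["survival"]
        low = res.curves["low"].set_index("time")["survival"]
        grid = sorted(set(high.index) | set(low.index))
        hi = high.reindex(grid).ffill().fillna(1.0)
        lo = low.reindex(grid).ffill().fillna(1.0)
        assert (hi <= lo + 1e-12).all()

    def test_median_ties_go_low_and_degenerate_split_errors(self):
        expr = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 5.0],
                         index=[f"s{i}" for i in range(6)])
        surv = _surv([1, 2, 3, 4, 5, 6], [1] * 6)
        res = km_logrank(expr, surv)
        # median 2.5 -> s0..s2 low, s3..s5 high; ties (2.0) in low
        assert (res.groups[["s1", "s2"]] == "low").all()
        flat = pd.Series([1.0] * 6, index=expr.index)
        with pytest.raises(ValueError, match="degenerate"):
            km_logrank(flat, surv)

    def test_group_relabel_symmetry(self):
        rng = np.random.default_rng(6)
        expr = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        surv = _surv(rng.exponential(10, 20) + 0.1, rng.random(20) < 0.8,
                     samples=list(expr.index))
        surv["event"] = surv["event"].astype(int)
        a = km_logrank(expr, surv)
        b = km_logrank(-expr, surv)  # groups swap
        assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_positive_time_required(self):
        expr = pd.Series([1, 2, 3, 4], index=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError, match="positive"):
            km_logrank(expr, _surv([1, 2, 0, 4], [1, 1, 1, 1]))


class TestSurvivalGenerator:
    def test_no_censoring_all_events(self):
        cfg = SynthConfig(seed=3, censor_rate=0.0)
        ds, _ = gen_expression(cfg)
        surv = gen_survival(cfg, ds, ds.gene_ids[0])
        assert (surv["event"] == 1).all()

    def test_power_at_strong_hazard(self):
        """hazard_beta=1.5, n=200: median-split log-rank rejects in most seeds."""
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SynthConfig(seed=seed, n_case=200, n_control=2, n_genes=50,
                              hazard_beta=1.5)
            ds, _ = gen_expression(cfg)
            gene = ds.gene_ids[0]
            surv = gen_survival(cfg, ds, gene)
            expr = ds.values.loc[gene, ds.samples_in("case")]
            res = km_logrank(expr, surv)
            rejections += res.p < 0.05
        assert rejections >= 0.8 * n_seeds

    def test_null_hazard_uniform_p(self):
        ps = []
        for seed in range(40):
            cfg = SynthConfig(seed=seed, n_case=60, n_genes=20, n_de=2,
                              hazard_beta=0.0)
            ds, _ = gen_expression(cfg)
            gene = ds.gene_ids[0]
            surv = gen_survival(cfg, ds, gene)
            expr = ds.values.loc[gene, ds.samples_in("case")]
            ps.append(km_logrank(expr, surv).p)
        assert 0.01 < np.mean(np.array(ps) < 0.5) < 0.99  # not degenerate
        assert np.mean(np.array(ps) < 0.05) < 0.25
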