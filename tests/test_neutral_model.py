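import math

import numpy as np
import pytest
from scipy import stats

from neutralcomm.core_io import CountTable, SampleMetadata, ValidationError, parse_lineage
from neutralcomm.neutral_model import (
    MetacommunitySummary,
    classify_otus,
    compare_models,
    compare_class_distinctness,
    fit_neutral,
    fit_per_group,
    predict_occurrence_binomial,
    predict_occurrence_neutral,
    prepare_metacommunity,
    prediction_band,
    taxonomic_distinctness,
    wilson_interval,
    _gaussian_aic,
)
from neutralcomm.synthetic_data import (
    SimulationConfig,
    sample_metacommunity,
    simulate_neutral_table,
)


def make_summary(p, f_obs, N=1000.0, n_local=30):
    p = np.asarray(p, dtype=float)
    return MetacommunitySummary(
        otu_ids=[f"o{i}" for i in range(len(p))],
        p=p,
        f_obs=np.asarray(f_obs, dtype=float),
        N=N,
        d=1.0 / N,
        n_local=n_local,
    )


class TestPrepareMetacommunity:
    def test_occurrence_half(self):
        t = CountTable(["s1", "s2"], ["a", "b"], np.array([[5, 5], [0, 10]]))
        s = prepare_metacommunity(t)
        assert s.f_obs[s.otu_ids.index("a")] == 0.5

    def test_uniform_table(self):
        t = CountTable(["s1", "s2"], ["a", "b"], np.array([[5, 5], [5, 5]]))
        s = prepare_metacommunity(t)
        np.testing.assert_allclose(s.p, [0.5, 0.5])
        np.testing.assert_allclose(s.f_obs, [1.0, 1.0])

    def test_four_sample_hand_arithmetic(self):
        counts = np.array([[10, 0], [20, 10], [30, 10], [0, 20]])
        t = CountTable([f"s{i}" for i in range(4)], ["a", "b"], counts)
        s = prepare_metacommunity(t)
        # totals: a=60, b=40, grand=100; sample totals 10,30,40,20 -> N=25
        np.testing.assert_allclose(s.p, [0.6, 0.4])
        np.testing.assert_allclose(s.f_obs, [0.75, 0.75])
        assert s.N == 25.0
        assert s.d == pytest.approx(1 / 25)
        assert s.n_local == 4

    def test_mean_of_proportions_option(self):
        counts = np.array([[10, 0], [5, 95]])
        t = CountTable(["s1", "s2"], ["a", "b"], counts)
        s = prepare_metacommunity(t, abundance="mean")
        np.testing.assert_allclose(s.p, [(1.0 + 0.05) / 2, 0.95 / 2])

    def test_single_sample_rejected(self):
        t = CountTable(["s1"], ["a"], np.array([[5]]))
        with pytest.raises(ValidationError, match="single sample"):
            prepare_metacommunity(t)

    def test_unobserved_otus_dropped(self):
        t = CountTable(["s1", "s2"], ["a", "ghost"], np.array([[5, 0], [5, 0]]))
        s = prepare_metacommunity(t)
        assert s.otu_ids == ["a"]
        assert s.p.sum() == pytest.approx(1.0)


class TestPredictNeutral:
    def test_closed_form_alpha_one(self):
        # N*m*p = 1 gives f_pred = (1-d)^beta exactly
        f = predict_occurrence_neutral(0.01, 1000, 0.1, 0.001)
        expected = (1 - 0.001) ** (1000 * 0.1 * 0.99)
        assert f == pytest.approx(expected, abs=1e-12)
        assert f == pytest.approx(0.9057, abs=1e-4)

    def test_m_to_zero_limit_is_p(self):
        for p in (0.1, 0.35, 0.8):
            f = predict_occurrence_neutral(p, 1000, 1e-6, 0.2)
            assert f == pytest.approx(p, abs=1e-3)

    def test_concentration_limit_one(self):
        assert predict_occurrence_neutral(0.5, 1e6, 1.0, 1e-4) == pytest.approx(1.0)

    def test_monotone_in_p_and_m(self):
        N, d = 10000.0, 1e-4
        ps = np.logspace(-5, -0.5, 40)
        for m in (0.01, 0.1, 0.5):
            f = predict_occurrence_neutral(ps, N, m, d)
            assert (np.diff(f) >= -1e-12).all()
        for p in ps[ps > d]:
            fs = [predict_occurrence_neutral(p, N, m, d) for m in (0.01, 0.05, 0.2, 0.8)]
            assert (np.diff(fs) >= -1e-9).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            predict_occurrence_neutral(0.5, 1000, 1.5, 0.001)
        with pytest.raises(ValidationError):
            predict_occurrence_neutral(0.0, 1000, 0.5, 0.001)


class TestPredictBinomial:
    def test_floor_cutoff_matches_direct_summation(self):
        N, p = 200, 0.03
        d = 1.0 / N
        f = predict_occurrence_binomial(p, N, d, detection="floor-cutoff")
        # 1 - P(X <= 1) by direct summation
        expected = 1 - sum(
            math.comb(N, k) * p**k * (1 - p) ** (N - k) for k in (0, 1)
        )
        assert f == pytest.approx(expected, abs=1e-12)

    def test_abundance_detection_is_one_read_at_d(self):
        N, p = 200, 0.03
        f = predict_occurrence_binomial(p, N, 1.0 / N)
        assert f == pytest.approx(1 - (1 - p) ** N, abs=1e-12)

    def test_p_one_gives_one(self):
        assert predict_occurrence_binomial(1.0, 100, 0.01) == pytest.approx(1.0)

    def test_p_zero_gives_zero(self):
        assert predict_occurrence_binomial(0.0, 100, 0.01) == 0.0


class TestFitNeutral:
    def _noiseless_summary(self, m=0.3, n_otus=60, N=5000.0, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(n_otus, 0.3))
        p = np.clip(p, 1e-8, None)
        p = p / p.sum()
        f_obs = predict_occurrence_neutral(p, N, m, 1.0 / N)
        return make_summary(p, f_obs, N=N)

    def test_self_consistency_noiseless(self):
        s = self._noiseless_summary(m=0.3)
        fit = fit_neutral(s)
        assert fit.m == pytest.approx(0.3, abs=1e-4)
        assert fit.r2_neutral == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_grid_search_brackets_optimum(self):
        rng = np.random.default_rng(1)
        s = self._noiseless_summary(m=0.2, seed=1)
        noisy = np.clip(s.f_obs + rng.normal(0, 0.05, len(s.f_obs)), 0, 1)
        s2 = make_summary(s.p, noisy, N=s.N)
        fit = fit_neutral(s2)
        grid = np.arange(0.001, 1.0001, 0.001)
        sse = [
            float(((s2.f_obs - predict_occurrence_neutral(s2.p, s2.N, m, s2.d)) ** 2).sum())
            for m in grid
        ]
        best = grid[int(np.argmin(sse))]
        assert abs(best - fit.m) <= 0.001  # grid point brackets the optimum

    def test_simulation_recovery(self):
        ok = 0
        for rep in range(15):
            cfg = SimulationConfig(n_taxa=300, n_samples=30, seed=1000 + rep)
            p = sample_metacommunity(cfg)
            t = simulate_neutral_table(p, 0.1, 50000, 30, 50000, seed=2000 + rep)
            fit = fit_neutral(prepare_metacommunity(t))
            ok += abs(fit.m - 0.1) / 0.1 <= 0.15
        assert ok >= 13

    def test_identical_occurrences_rejected(self):
        s = make_summary([0.5, 0.3, 0.2], [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="identical"):
            fit_neutral(s)

    def test_few_otus_warn(self):
        s = make_summary([0.6, 0.4], [0.9, 0.5])
        with pytest.warns(UserWarning, match="OTUs"):
            fit_neutral(s)

    def test_aic_penalty_arithmetic(self):
        # identical SSE differs only by the parameter count penalty
        assert _gaussian_aic(1.0, 50, 2) - _gaussian_aic(1.0, 50, 1) == pytest.approx(2.0)


class TestClassify:
    def test_on_curve_is_neutral(self):
        s = TestFitNeutral()._noiseless_summary(m=0.25)
        fit = fit_neutral(s)
        assert set(fit.classes) == {"neutral"}
        assert fit.neutral_fraction == 1.0

    def test_forced_above(self):
        s = TestFitNeutral()._noiseless_summary(m=0.25)
        f_obs = s.f_obs.copy()
        # push one mid-curve OTU to permanent occupancy
        i = int(np.argmin(np.abs(f_obs - 0.5)))
        f_obs[i] = 1.0
        fit = fit_neutral(make_summary(s.p, f_obs, N=s.N))
        assert fit.classes[i] == "above"

    def test_fractions_sum_to_one(self):
        cfg = SimulationConfig(n_taxa=200, n_samples=25, seed=5)
        p = sample_metacommunity(cfg)
        t = simulate_neutral_table(p, 0.2, 30000, 25, 30000, seed=6)
        fit = fit_neutral(prepare_metacommunity(t))
        total = fit.neutral_fraction + fit.above_fraction + fit.below_fraction
        assert total == pytest.approx(1.0)

    def test_invariant_to_otu_order(self):
        cfg = SimulationConfig(n_taxa=150, n_samples=20, seed=9)
        p = sample_metacommunity(cfg)
        t = simulate_neutral_table(p, 0.2, 20000, 20, 20000, seed=10)
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.n_otus)
        t2 = CountTable(
            list(t.sample_ids), [t.otu_ids[j] for j in perm], t.counts[:, perm]
        )
        f1 = fit_neutral(prepare_metacommunity(t))
        f2 = fit_neutral(prepare_metacommunity(t2))
        # summation order perturbs m-hat in its last digits, which can flip
        # a single boundary OTU; allow a one-OTU discrepancy
        n = len(f1.classes)
        assert abs(f1.neutral_fraction - f2.neutral_fraction) <= 1.5 / n
        assert f1.m == pytest.approx(f2.m, rel=1e-6)

    def test_level_validation(self):
        s = TestFitNeutral()._noiseless_summary()
        fit = fit_neutral(s)
        with pytest.raises(ValidationError, match="95 or 99"):
            classify_otus(s, fit, level=90)
        classes, fractions = classify_otus(s, fit, level=90, allow_any_level=True)
        assert len(classes) == len(s.p)

    def test_prediction_band_option(self):
        # the band is an acceptance region for attainable (discrete)
        # occurrence frequencies, so snap the noiseless curve to k/n first
        s = TestFitNeutral()._noiseless_summary()
        f_obs = np.round(s.f_obs * s.n_local) / s.n_local
        s2 = make_summary(s.p, f_obs, N=s.N, n_local=s.n_local)
        fit = fit_neutral(s2)
        classes, fractions = classify_otus(s2, fit, level=95, interval="prediction")
        assert fractions["neutral"] == 1.0


class TestIntervals:
    def test_wilson_in_unit_interval_and_contains_estimate(self):
        rng = np.random.default_rng(3)
        p_hat = rng.random(200)
        lo, hi = wilson_interval(p_hat, 30, 95)
        assert (lo >= 0).all() and (hi <= 1).all()
        assert ((p_hat >= lo) & (p_hat <= hi)).all()

    def test_wilson_level_ordering(self):
        lo95, hi95 = wilson_interval(0.4, 30, 95)
        lo99, hi99 = wilson_interval(0.4, 30, 99)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_prediction_band_calibrated_at_boundary(self):
        # ubiquitous OTU: f_pred near 1, observed occupancy 1 stays inside
        lo, hi = prediction_band(0.985, 30, 95)
        assert hi == 1.0
        # whereas the Wilson band around the same prediction excludes 1
        _, hi_w = wilson_interval(0.985, 30, 95)
        assert hi_w < 1.0


class TestCompareModels:
    def test_neutral_preferred_on_neutral_data(self):
        cfg = SimulationConfig(n_taxa=250, n_samples=30, seed=21)
        p = sample_metacommunity(cfg)
        t = simulate_neutral_table(p, 0.1, 40000, 30, 40000, seed=22)
        table = compare_models(prepare_metacommunity(t))
        aic = table.set_index("model")["AIC"]
        assert aic["neutral"] < aic["binomial"]
        assert table["dAIC"].min() == 0.0


class TestFitPerGroup:
    def _grouped_table(self):
        cfg = SimulationConfig(n_taxa=150, n_samples=20, seed=31)
        p = sample_metacommunity(cfg)
        t1 = simulate_neutral_table(
            p, 0.1, 20000, 10, 20000, seed=32, sample_ids=[f"a{i}" for i in range(10)]
        )
        t2 = CountTable([f"b{i}" for i in range(10)], list(t1.otu_ids), t1.counts.copy())
        counts = np.vstack([t1.counts, t2.counts])
        table = CountTable(list(t1.sample_ids) + list(t2.sample_ids), list(t1.otu_ids), counts)
        meta = SampleMetadata(
            {s: {"location": "east" if s.startswith("a") else "west", "species": "X"}
             for s in table.sample_ids}
        )
        return table, meta

    def test_identical_groups_identical_fits(self):
        table, meta = self._grouped_table()
        fits, summary = fit_per_group(table, meta, "location", level=99)
        assert fits["east"].m == pytest.approx(fits["west"].m)
        assert fits["east"].neutral_fraction == fits["west"].neutral_fraction

    def test_mean_is_arithmetic_mean(self):
        table, meta = self._grouped_table()
        fits, summary = fit_per_group(table, meta, "location", level=99)
        vals = [fits[g].neutral_fraction for g in fits]
        assert all(0 <= v <= 1 for v in vals)
        assert summary["mean_neutral_fraction"] == pytest.approx(float(np.mean(vals)))

    def test_small_groups_skipped_with_warning(self):
        table, meta = self._grouped_table()
        meta.records["a0"]["location"] = "lonely"
        with pytest.warns(UserWarning, match="lonely"):
            fits, _ = fit_per_group(table, meta, "location", level=99)
        assert "lonely" not in fits


class TestTaxonomicDistinctness:
    def test_same_genus_minimal(self):
        lins = [
            parse_lineage("k__A; p__B; c__C; o__D; f__E; g__G; s__s1"),
            parse_lineage("k__A; p__B; c__C; o__D; f__E; g__G; s__s2"),
        ]
        assert taxonomic_distinctness(lins) == pytest.approx(100 / 7)

    def test_distinct_kingdoms_maximal(self):
        lins = [parse_lineage("k__A"), parse_lineage("k__B"), parse_lineage("k__C")]
        assert taxonomic_distinctness(lins) == pytest.approx(100.0)

    def test_identical_lineages_zero(self):
        lins = [parse_lineage("k__A; p__B; c__C; o__D; f__E; g__G; s__S")] * 3
        assert taxonomic_distinctness(lins) == 0.0

    def test_four_lineage_hand_enumeration(self):
        l1 = parse_lineage("k__A; p__B; c__C; o__D; f__E; g__G; s__S1")
        l2 = parse_lineage("k__A; p__B; c__C; o__D; f__E; g__G; s__S2")  # shares 6
        l3 = parse_lineage("k__A; p__B; c__X")  # shares 2 with l1/l2
        l4 = parse_lineage("k__Z")  # shares 0 with all
        # pairwise shared depths: (l1,l2)=6, (l1,l3)=(l2,l3)=2, rest 0
        dist = lambda s: 100 * (7 - s) / 7
        expected = (dist(6) + dist(2) + dist(2) + dist(0) * 3) / 6
        assert taxonomic_distinctness([l1, l2, l3, l4]) == pytest.approx(expected)

    def test_bootstrap_comparison_runs(self):
        classes = {
            "neutral": [parse_lineage(f"k__A; p__P{i % 4}") for i in range(10)],
            "above": [parse_lineage("k__A; p__P0")] * 4,
        }
        table = compare_class_distinctness(classes, n_bootstrap=99, seed=0)
        assert set(table["class"]) == {"neutral", "above"}
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()


class TestRobustnessToRarefaction:
    def test_m_stable_after_rarefying(self):
        from neutralcomm.diversity import rarefy_table

        cfg = SimulationConfig(n_taxa=250, n_samples=30, seed=41)
        p = sample_metacommunity(cfg)
        t = simulate_neutral_table(
            p, 0.1, 30000, 30, np.random.default_rng(42).integers(25000, 35000, 30), seed=43
        )
        depth = int(t.sample_totals().min())
        t_rare = rarefy_table(t, depth, seed=44)
        s_full = prepare_metacommunity(t)
        s_rare = prepare_metacommunity(t_rare)
        fit_full = fit_neutral(s_full, ci_level=99.0)
        fit_rare = fit_neutral(s_rare, ci_level=99.0)
        # rarefying changes the effective community size N, so the stable
        # quantities are the composite N*m and the neutral fraction
        nm_full = s_full.N * fit_full.m
        nm_rare = s_rare.N * fit_rare.m
        assert abs(nm_full - nm_rare) / nm_full < 0.15
        assert abs(fit_full.neutral_fraction - fit_rare.neutral_fraction) < 0.1
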