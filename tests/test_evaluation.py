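import numpy as np
import pytest

from updrs_abbrev import (
    IntervalEstimate,
    ItemSet,
    LinearModel,
    SimConfig,
    bland_altman,
    bootstrap_interval,
    compute_metrics,
    compute_suffstats,
    conditional_distribution,
    evaluate_fixed_subset,
    evs_subset,
    fit_sum_model,
    generate,
    generate_pair,
    interval_overlap,
    predict_total,
    residual_analysis,
    transfer_evaluate,
)

from conftest import make_table


class TestFitSumModel:
    def test_noiseless_recovery(self, linear_exact_table):
        table, subset = linear_exact_table
        model = fit_sum_model(table, subset)
        assert model.slope == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(7.0, abs=1e-12)
        assert model.n_fit == len(table)

    def test_mean_residual_is_zero_on_own_data(self, registry, small_table):
        subset = ItemSet(["1.13", "2.5", "2.10", "3.4"])
        model = fit_sum_model(small_table, subset)
        resid = small_table.total_scores() - model.predict(
            small_table.subset_sums(subset)
        )
        assert abs(resid.mean()) < 1e-10

    def test_matches_normal_equations_oracle(self, registry):
        rng = np.random.default_rng(31)
        table = make_table(
            registry,
            {
                "1.1": rng.integers(0, 5, 20).tolist(),
                "2.10": rng.integers(0, 5, 20).tolist(),
                "3.9": rng.integers(0, 5, 20).tolist(),
            },
        )
        subset = ItemSet(["1.1", "2.10"])
        model = fit_sum_model(table, subset)
        x = table.subset_sums(subset).to_numpy()
        y = table.total_scores().to_numpy()
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_predictor_rejected(self, registry, table_factory):
        table = table_factory({"1.1": [1, 3, 2], "2.5": [2, 2, 2]})
        with pytest.raises(ValueError, match="zero variance"):
            fit_sum_model(table, ItemSet(["2.5"]))


class TestPredictTotal:
    def test_intercept_at_zero(self):
        model = LinearModel(2.0, 7.0, ItemSet(["1.1"]), 10)
        assert predict_total(model, 0) == 7.0
        assert predict_total(model, 10) == 27.0

    def test_published_coefficients(self):
        """The published remote-subset conversion: y = 4.87 x + 5.59."""
        model = LinearModel(4.87, 5.59, ItemSet(["1.1"]), 7594)
        assert predict_total(model, 10) == pytest.approx(54.29)


class TestComputeMetrics:
    def test_perfect_agreement(self):
        a = np.array([3.0, 10.0, 7.0, 1.0, 5.0])
        m = compute_metrics(a, a)
        assert m.evs == pytest.approx(1.0, abs=1e-12)
        assert m.pcc == pytest.approx(1.0, abs=1e-12)
        assert m.src == pytest.approx(1.0, abs=1e-12)
        assert m.pcc_p < 0.01 and m.src_p < 0.01

    def test_anticorrelation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(a, -a)
        assert m.pcc == pytest.approx(-1.0)
        assert m.src == pytest.approx(-1.0)

    def test_spearman_with_ties_matches_midrank_oracle(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        e = [2.0, 1.0, 4.0, 4.0, 6.0, 7.0]

        def midranks(v):
            v = np.asarray(v)
            out = np.empty(len(v))
            order = np.argsort(v, kind="stable")
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and v[order[j]] == v[order[i]]:
                    j += 1
                out[order[i:j]] = (i + j + 1) / 2  # average of ranks i+1..j
                i = j
            return out

        ra, re = midranks(a), midranks(e)
        oracle = np.corrcoef(ra, re)[0, 1]
        assert compute_metrics(a, e).src == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 3"):
            compute_metrics([1.0, 2.0], [1.0, 2.0])

    def test_evs_consistent_with_search_closed_form(self, registry, small_table):
        """Cross-module identity: metric EVS of the fitted model equals the
        sufficient-statistics closed form used by the search."""
        subset = ItemSet(["1.13", "2.10", "3.4", "3.9", "4.3"])
        stats = compute_suffstats(small_table, registry)
        model = fit_sum_model(small_table, subset)
        y = small_table.total_scores().to_numpy()
        pred = model.predict(small_table.subset_sums(subset).to_numpy())
        assert compute_metrics(y, pred).evs == pytest.approx(
            evs_subset(stats, subset), abs=1e-10
        )


class TestBootstrapInterval:
    def test_seed_determinism(self, registry, small_table):
        subset = ItemSet(["1.13", "2.10", "3.4"])
        kw = dict(n_boot=300, seed=42)
        a = bootstrap_interval("pcc", small_table, subset, **kw)
        b = bootstrap_interval("pcc", small_table, subset, **kw)
        c = bootstrap_interval("pcc", small_table, subset, n_boot=300, seed=43)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_degenerate_statistic_collapses(self, registry, table_factory):
        table = table_factory({"1.1": [2, 2, 2, 2, 2]})
        iv = bootstrap_interval(
            "median", table, ItemSet(["1.1"]), n_boot=200, seed=0
        )
        assert iv.lower == iv.point == iv.upper == 2.0

    def test_interval_brackets_point_and_narrows_with_n(self, registry):
        subset = ItemSet(["1.13", "2.5", "2.10", "3.4"])
        widths = []
        for n in (200, 2000):
            wins = 0
            for seed in range(5):
                table = generate(SimConfig(n_records=n, seed=seed), registry)
                iv = bootstrap_interval(
                    "evs", table, subset, n_boot=400, seed=seed
                )
                assert iv.lower <= iv.point <= iv.upper
                wins += iv.width
            widths.append(wins / 5)
        assert widths[1] < widths[0]

    def test_unknown_statistic_rejected(self, registry, small_table):
        with pytest.raises(ValueError, match="unknown bootstrap statistic"):
            bootstrap_interval("kurtosis", small_table, ItemSet(["1.1"]))

    def test_small_n_boot_rejected(self, registry, small_table):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_interval(
                "pcc", small_table, ItemSet(["1.1"]), n_boot=50
            )


class TestIntervalOverlap:
    def test_cases(self):
        iv = lambda lo, hi: IntervalEstimate(point=(lo + hi) / 2, lower=lo, upper=hi)
        assert interval_overlap(iv(0.80, 0.86), iv(0.83, 0.88))
        assert not interval_overlap(iv(0.1, 0.2), iv(0.3, 0.4))
        assert interval_overlap(iv(0.0, 1.0), iv(1.0, 2.0))  # closed endpoints

    def test_mismatched_levels_rejected(self):
        a = IntervalEstimate(0.5, 0.4, 0.6, level=0.95)
        b = IntervalEstimate(0.5, 0.4, 0.6, level=0.90)
        with pytest.raises(ValueError, match="level"):
            interval_overlap(a, b)


class TestResidualAnalysis:
    def test_zero_mean_on_own_data(self, registry, small_table):
        subset = ItemSet(["1.13", "2.10", "3.4", "4.3"])
        model = fit_sum_model(small_table, subset)
        summary = residual_analysis(model, small_table, n_boot=200)
        assert abs(summary.mean_residual) < 1e-10
        assert summary.mean_residual_interval.contains(0.0)
        assert summary.residuals_by_actual["n"].sum() == len(small_table)

    def test_translation_shifts_mean_residual(self, registry, small_table):
        subset = ItemSet(["1.13", "2.10", "3.4", "4.3"])
        model = fit_sum_model(small_table, subset)
        shifted = LinearModel(
            model.slope, model.intercept - 3.0, subset, model.n_fit
        )
        summary = residual_analysis(shifted, small_table, n_boot=200)
        assert summary.mean_residual == pytest.approx(3.0, abs=1e-10)

    def test_convex_truth_underestimated_at_high_end(self, registry):
        """y = x^2: a straight line under-estimates the extremes, so the
        top actual-score band shows positive mean residual."""
        x = [0, 1, 2, 3, 4] * 4
        table = make_table(registry, {
            "1.1": x,
            "1.2": [min(4, v * v) for v in x],          # x^2 = 0,1,4,9,16
            "1.3": [max(0, min(4, v * v - 4)) for v in x],
            "1.4": [max(0, min(4, v * v - 8)) for v in x],
            "1.5": [max(0, v * v - 12) for v in x],
        })
        subset = ItemSet(["1.1"])
        model = fit_sum_model(table, subset)
        summary = residual_analysis(model, table, n_boot=200, band_width=5)
        bands = summary.residuals_by_actual
        top = bands.iloc[bands["band_lo"].idxmax()]
        assert top["mean_residual"] > 0
        assert summary.skewness > 0  # right-skewed residuals


class TestBlandAltman:
    def test_identity(self):
        a = np.array([1.0, 5.0, 9.0, 2.0])
        s = bland_altman(a, a)
        assert (s.bias, s.loa_lower, s.loa_upper) == (0.0, 0.0, 0.0)
        assert s.proportional_bias_slope == 0.0

    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0])
        s = bland_altman(a, a + 5.0)
        assert s.bias == pytest.approx(-5.0)  # orientation actual - estimated
        assert s.proportional_bias_slope == pytest.approx(0.0, abs=1e-12)
        assert s.loa_lower == pytest.approx(-5.0)
        assert s.loa_upper == pytest.approx(-5.0)

    def test_ten_pair_fixture_matches_hand_formula(self):
        actual = np.array([12.0, 45, 33, 60, 21, 18, 50, 39, 27, 44])
        est = np.array([15.0, 40, 30, 66, 20, 22, 45, 42, 25, 41])
        s = bland_altman(actual, est)
        diff = actual - est
        assert s.bias == pytest.approx(diff.sum() / 10)
        sd = np.sqrt(((diff - diff.mean()) ** 2).sum() / 9)
        assert s.loa_lower == pytest.approx(diff.mean() - 1.96 * sd)
        assert s.loa_upper == pytest.approx(diff.mean() + 1.96 * sd)
        assert s.loa_lower <= s.bias <= s.loa_upper

    def test_bias_equals_mean_residual(self, registry, small_table):
        subset = ItemSet(["1.13", "2.10", "3.4"])
        model = fit_sum_model(small_table, subset)
        y = small_table.total_scores().to_numpy()
        pred = model.predict(small_table.subset_sums(subset).to_numpy())
        s = bland_altman(y, pred)
        assert s.bias == pytest.approx(float((y - pred).mean()), abs=1e-12)


class TestConditionalDistribution:
    def test_single_group(self, registry, table_factory):
        table = table_factory({"1.1": [2] * 7, "2.5": [0, 1, 2, 3, 4, 0, 2]})
        cond = conditional_distribution(table, ItemSet(["1.1"]))
        assert len(cond.table) == 1
        assert cond.table.loc[0, "n"] == 7

    def test_identical_totals_collapse_percentiles(self, registry, table_factory):
        table = table_factory({"1.1": [3] * 6})
        cond = conditional_distribution(table, ItemSet(["1.1"]))
        row = cond.table.iloc[0]
        assert row["p2.5"] == row["p25"] == row["p50"] == row["p75"] == row["p97.5"] == 3

    def test_percentiles_match_interpolation_oracle(self, registry):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 5, size=(20, 4))
        table = make_table(registry, {
            "1.1": [1] * 20,
            "1.2": vals[:, 0].tolist(),
            "1.3": vals[:, 1].tolist(),
            "1.4": vals[:, 2].tolist(),
            "1.5": vals[:, 3].tolist(),
        })
        cond = conditional_distribution(table, ItemSet(["1.1"]))
        totals = np.sort(table.total_scores().to_numpy())

        def interp_percentile(sorted_v, q):  # linear between order statistics
            h = (len(sorted_v) - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_v) - 1)
            return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

        row = cond.table.iloc[0]
        for q, col in [(2.5, "p2.5"), (25, "p25"), (50, "p50"),
                       (75, "p75"), (97.5, "p97.5")]:
            assert row[col] == pytest.approx(interp_percentile(totals, q))

    def test_group_sizes_conserve_and_suppression_flags(self, registry):
        table = generate(SimConfig(n_records=400, seed=2), registry)
        cond = conditional_distribution(table, ItemSet(["1.13", "2.10"]), 5)
        assert cond.table["n"].sum() == 400
        assert (cond.displayed["n"] >= 5).all()
        within = cond.table[["p2.5", "p25", "p50", "p75", "p97.5"]].to_numpy()
        assert (np.diff(within, axis=1) >= 0).all()


class TestTransferAndFixedSubsets:
    def test_identical_cohorts_trivially_overlap(self, registry, small_table):
        subset = ItemSet(["1.13", "2.5", "2.10", "3.4"])
        model = fit_sum_model(small_table, subset)
        report = transfer_evaluate(
            model, subset, small_table, small_table, n_boot=200, seed=1
        )
        assert report.train_metrics == report.validation_metrics
        assert all(report.overlap.values())

    def test_exchangeable_validation_residual_interval_crosses_zero(self, registry):
        """With no severity shift the cohorts are exchangeable, so the
        train-fitted model is unbiased on validation: the 95% interval of
        the mean residual should cross zero in ~95% of replicates."""
        subset = ItemSet(["1.13", "2.5", "2.10", "2.12", "3.2", "3.4", "3.9", "4.3"])
        covered = 0
        for seed in range(10):
            cfg = SimConfig(n_records=800, seed=seed, validation_shift=0.0)
            train, val = generate_pair(cfg, registry)
            model = fit_sum_model(train, subset)
            iv = bootstrap_interval(
                "mean_residual", val, subset, n_boot=400, seed=seed, model=model
            )
            covered += iv.contains(0.0)
        assert covered >= 7

    def test_severity_shift_induces_positive_transfer_bias(self, registry):
        """The ordinal clipping makes E[total | subset sum] mildly convex,
        so on a more severe cohort the train-fitted line under-estimates:
        validation mean residual is positive, while EVS intervals still
        overlap."""
        cfg = SimConfig(n_records=800, seed=14, validation_shift=0.4)
        train, val = generate_pair(cfg, registry)
        subset = ItemSet(["1.13", "2.5", "2.10", "2.12", "3.2", "3.4", "3.9", "4.3"])
        model = fit_sum_model(train, subset)
        report = transfer_evaluate(model, subset, train, val, n_boot=400, seed=3)
        assert report.validation_residuals.mean_residual > 0
        assert report.overlap["evs"]

    def test_rank_one_subset_beats_other_candidates(self, registry, small_table):
        from updrs_abbrev import SearchConfig, exhaustive_search

        stats = compute_suffstats(small_table, registry)
        pool = ItemSet(["1.13", "2.5", "2.10", "3.4", "3.9", "4.3"])
        results = exhaustive_search(stats, SearchConfig(pool=pool, k=2, top_k=15))
        best_evs = evaluate_fixed_subset(small_table, results.best.subset).evs
        for r in results:
            assert best_evs >= evaluate_fixed_subset(small_table, r.subset).evs - 1e-10

    def test_noise_items_score_near_zero(self, registry):
        noise = ItemSet(["1.3", "4.1"])
        cfg = SimConfig(
            n_records=1500, seed=8,
            item_loadings={"1.3": 0.0, "4.1": 0.0},
        )
        table = generate(cfg, registry)
        assert evaluate_fixed_subset(table, noise).evs < 0.1

    def test_full_registry_is_perfect(self, registry, small_table):
        m = evaluate_fixed_subset(small_table, ItemSet(registry.item_ids))
        assert m.evs == pytest.approx(1.0, abs=1e-12)
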