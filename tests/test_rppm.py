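"""RPPM quantification: filtering, master/local 5PL fits, FDR rejection,
y-intercept readout."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rmtbi_markers.fivepl import FivePL, eval_5pl
from rmtbi_markers.rppm import (
    DataError,
    DilutionSeries,
    FilterThresholds,
    FitError,
    LocalBlockFit,
    build_series,
    compute_net_fluorescence,
    fdr_outlier_mask,
    filter_spots,
    fit_local_block,
    fit_master_curve,
    pool_points,
    quantify_sample,
    quantify_slide,
    refine_master,
    summarize_groups,
)
from rmtbi_markers.synthetic import SlideSimConfig, simulate_rppm_slide


def _spot_row(**kw):
    base = dict(sample_id="S", block_id="B", dilution_step=0, deposition=0,
                raw=100.0, background=40.0, snr=5.0)
    base.update(kw)
    return base


class TestFiltering:
    def test_net_is_raw_minus_background(self):
        df = pd.DataFrame([_spot_row(raw=100, background=40),
                           _spot_row(raw=40, background=40),
                           _spot_row(raw=10, background=25)])
        net = compute_net_fluorescence(df)["net"]
        assert net.tolist() == [60.0, 0.0, -15.0]

    def test_non_finite_rejected(self):
        df = pd.DataFrame([_spot_row(raw=np.inf)])
        with pytest.raises(DataError):
            compute_net_fluorescence(df)

    @pytest.mark.parametrize("snr,net,kept", [
        (1.9, 500.0, False),   # SNR just below threshold
        (5.0, 9.0, False),     # net just below threshold
        (2.0, 10.0, True),     # both exactly at threshold: strict "<" keeps
        (5.0, -15.0, False),   # negative net removed here
    ])
    def test_strict_threshold_boundaries(self, snr, net, kept):
        df = pd.DataFrame([_spot_row(snr=snr, raw=net + 40.0, background=40.0)])
        k, e = filter_spots(df, FilterThresholds())
        assert (len(k) == 1) is kept
        assert len(k) + len(e) == 1

    def test_partition_is_exact(self, noisy_slide):
        spots, _, _ = noisy_slide
        kept, excluded = filter_spots(compute_net_fluorescence(spots))
        assert len(kept) + len(excluded) == len(spots)
        assert set(kept.index).isdisjoint(excluded.index)

    def test_planted_subthreshold_exactly_excluded(self):
        cfg = SlideSimConfig(n_samples=12, subthreshold_fraction=0.08, seed=7)
        spots, truth = simulate_rppm_slide(cfg)
        _, excluded = filter_spots(compute_net_fluorescence(spots))
        assert set(excluded.index) == set(truth.payload["subthreshold_rows"])

    def test_empty_input_empty_outputs(self):
        df = pd.DataFrame(columns=["sample_id", "block_id", "dilution_step",
                                   "deposition", "raw", "background", "snr"])
        k, e = filter_spots(compute_net_fluorescence(df))
        assert len(k) == 0 and len(e) == 0

    def test_depositions_averaged_after_filtering(self):
        rows = [_spot_row(raw=140.0, deposition=0),
                _spot_row(raw=160.0, deposition=1),
                _spot_row(raw=1040.0, deposition=2, snr=1.0)]  # filtered out
        kept, _ = filter_spots(compute_net_fluorescence(pd.DataFrame(rows)))
        series = build_series(kept)
        assert len(series) == 1
        assert series[0].y[0] == pytest.approx(np.log10(110.0))


class TestMasterFit:
    def test_noise_free_recovery_exact(self, noise_free_slide, truth_params):
        spots, _, _ = noise_free_slide
        # use the unit-abundance pooled condition for the exactness check
        cfg = SlideSimConfig(n_samples=4, noise_sigma=0.0, seed=0)
        spots, _ = simulate_rppm_slide(cfg)
        kept, _ = filter_spots(compute_net_fluorescence(spots))
        x, y = pool_points(build_series(kept))
        fit = fit_master_curve(x, y)
        for k in "ADCBG":
            got, want = getattr(fit.params, k), getattr(truth_params, k)
            assert abs(got - want) / abs(want) < 1e-6

    def test_noisy_recovery_within_ten_percent(self, noisy_slide, truth_params):
        spots, _, _ = noisy_slide
        kept, _ = filter_spots(compute_net_fluorescence(spots))
        x, y = pool_points(build_series(kept))
        fit = fit_master_curve(x, y)
        for k in "ADCBG":
            got, want = getattr(fit.params, k), getattr(truth_params, k)
            assert abs(got - want) / abs(want) < 0.10

    def test_too_few_points_raises(self):
        with pytest.raises(FitError):
            fit_master_curve(np.array([0.0, -1.0]), np.array([3.0, 2.0]))

    def test_too_few_distinct_positions_raises(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, -1.0, -1.0, -1.0, -1.0])
        with pytest.raises(FitError):
            fit_master_curve(x, np.ones(8))


class TestFdrOutliers:
    def test_singleton_outlier_flagged(self):
        r = np.zeros(50)
        r[17] = 5.0
        mask = fdr_outlier_mask(r, q=0.01)
        assert mask[17] and mask.sum() == 1

    def test_all_zero_residuals_empty_mask(self):
        assert fdr_outlier_mask(np.zeros(20), q=0.01).sum() == 0

    def test_null_flag_rate_controlled(self):
        rng = np.random.default_rng(0)
        flagged = total = 0
        for _ in range(100):
            r = rng.normal(0, 1, 200)
            flagged += fdr_outlier_mask(r, q=0.01).sum()
            total += 200
        assert flagged / total <= 0.05

    def test_sensitivity_to_planted_tenfold_outliers(self):
        # residuals in log10: a 10x intensity outlier is +1
        rng = np.random.default_rng(1)
        hits = planted = 0
        for _ in range(100):
            r = rng.normal(0, 0.02, 200)
            idx = rng.choice(200, 10, replace=False)
            r[idx] += 1.0
            mask = fdr_outlier_mask(r, q=0.01)
            hits += mask[idx].sum()
            planted += 10
        assert hits / planted >= 0.9

    def test_too_few_residuals_raises(self):
        with pytest.raises(FitError):
            fdr_outlier_mask(np.zeros(5), q=0.01)


class TestRefinement:
    def _master(self, spots):
        kept, _ = filter_spots(compute_net_fluorescence(spots))
        x, y = pool_points(build_series(kept))
        return fit_master_curve(x, y)

    def test_clean_slide_is_fixed_point(self):
        spots, _ = simulate_rppm_slide(SlideSimConfig(n_samples=4,
                                                      noise_sigma=0.0, seed=0))
        fit = self._master(spots)
        refined = refine_master(fit)
        assert refined.n_refinement_rounds == 1
        assert refined.outlier_mask.sum() == 0
        for k in "ADCBG":
            assert getattr(refined.params, k) == pytest.approx(
                getattr(fit.params, k), rel=1e-6)

    def test_outliers_removed_params_improve(self, truth_params):
        spots, truth = simulate_rppm_slide(SlideSimConfig(
            n_samples=16, noise_sigma=0.02, outlier_fraction=0.03,
            outlier_scale=10.0, seed=2))
        fit = self._master(spots)
        refined = refine_master(fit)

        def err(p):
            return max(abs(getattr(p, k) - getattr(truth_params, k))
                       / abs(getattr(truth_params, k)) for k in "ADCBG")
        assert err(refined.params) < err(fit.params)
        assert refined.outlier_mask.sum() > 0

    def test_kept_rss_never_increases(self):
        spots, _ = simulate_rppm_slide(SlideSimConfig(
            n_samples=16, noise_sigma=0.02, outlier_fraction=0.05, seed=4))
        fit = self._master(spots)
        refined = refine_master(fit)
        kept = ~refined.outlier_mask
        r_before = (eval_5pl(refined.x[kept], fit.params) - refined.y[kept])
        assert refined.kept_rss <= float(r_before @ r_before) + 1e-12


class TestLocalBlock:
    def _series(self, abundances, sigma=0.0, seed=0):
        cfg = SlideSimConfig(n_samples=len(abundances), noise_sigma=sigma,
                             true_abundance=abundances,
                             samples_per_block=len(abundances), seed=seed)
        spots, _ = simulate_rppm_slide(cfg)
        kept, _ = filter_spots(compute_net_fluorescence(spots))
        return build_series(kept)

    def test_identical_series_give_equal_positions(self, truth_params):
        series = self._series([1.0, 1.0, 1.0])
        fit = fit_local_block(series, truth_params)
        cs = list(fit.positions.values())
        assert max(cs) - min(cs) < 1e-6

    def test_doubling_abundances_space_positions_by_one(self, truth_params):
        series = self._series([1.0, 2.0, 4.0])
        fit = fit_local_block(series, truth_params)
        cs = [fit.positions[f"S{i:03d}"] for i in range(3)]
        assert cs[0] - cs[1] == pytest.approx(1.0, abs=1e-6)
        assert cs[1] - cs[2] == pytest.approx(1.0, abs=1e-6)

    def test_noise_free_shared_params_equal_truth(self, truth_params):
        series = self._series([1.0, 2.0, 4.0])
        fit = fit_local_block(series, truth_params)
        for k in "ADBG":
            got, want = getattr(fit.shared, k), getattr(truth_params, k)
            assert abs(got - want) / abs(want) < 1e-6

    def test_single_sample_block_allowed(self, truth_params):
        series = self._series([1.0])
        fit = fit_local_block(series, truth_params)
        assert len(fit.positions) == 1

    def test_short_series_rejected(self, truth_params):
        s = DilutionSeries(sample_id="S", block_id="B",
                           x=np.array([0.0, -1.0]), y=np.array([3.0, 2.5]),
                           usable=np.array([True, True]))
        with pytest.raises(FitError):
            fit_local_block([s], truth_params)


class TestQuantification:
    def test_exact_line_slope_and_intercept(self):
        # collinear points at steps 1..3; a wide-band local fit keeps all
        p = FivePL(A=0.0, D=16.0, C=-2.0, B=1.0, G=1.0)
        local = LocalBlockFit(block_id="B", shared=p, positions={"S": -2.0},
                              rss=0.0)
        s = DilutionSeries(sample_id="S", block_id="B",
                           x=np.array([-1.0, -2.0, -3.0]),
                           y=np.array([9.0, 8.0, 7.0]),
                           usable=np.ones(3, bool))
        q = quantify_sample(s, local)
        assert q.linear_slope == pytest.approx(1.0, abs=1e-12)   # -1 per step
        assert q.y_intercept == pytest.approx(10.0, abs=1e-12)

    def test_doubling_abundance_shifts_intercept_by_slope(self):
        # frozen from the analytic band oracle for the default truth curve:
        # the integer-step selection shifts rigidly, so the intercept moves
        # by exactly one slope unit (0.5427 log10 per log2) per doubling
        cfg = SlideSimConfig(n_samples=2, noise_sigma=0.0,
                             true_abundance=[1.0, 2.0], seed=0)
        spots, _ = simulate_rppm_slide(cfg)
        res = quantify_slide(spots)
        q = res.quantifications.set_index("sample_id")
        shift = q.loc["S001", "y_intercept"] - q.loc["S000", "y_intercept"]
        assert shift == pytest.approx(0.542691683355, abs=1e-4)
        assert shift == pytest.approx(q.loc["S000", "linear_slope"], abs=1e-4)

    def test_noise_free_intercept_matches_band_oracle(self):
        spots, _ = simulate_rppm_slide(SlideSimConfig(
            n_samples=4, noise_sigma=0.0, seed=0))
        res = quantify_slide(spots)
        # frozen from an independent numpy oracle (band selection + polyfit
        # on the analytic curve)
        assert res.quantifications["y_intercept"].to_numpy() == pytest.approx(
            np.full(4, 5.501559810019), abs=1e-4)

    def test_too_few_band_points_marked_unusable(self):
        p = FivePL(A=0.0, D=10.0, C=0.0, B=1.0, G=1.0)
        local = LocalBlockFit(block_id="B", shared=p, positions={"S": 0.0},
                              rss=0.0)
        # all observed points sit on the lower asymptote, outside the band
        s = DilutionSeries(sample_id="S", block_id="B",
                           x=np.array([-20.0, -21.0, -22.0]),
                           y=np.array([0.0, 0.0, 0.0]),
                           usable=np.ones(3, bool))
        q = quantify_sample(s, local)
        assert not q.usable
        assert np.isnan(q.y_intercept)


class TestEndToEnd:
    def test_noise_free_rank_recovery_exact(self):
        # abundances 0.5 log2 apart: the discrete band selection biases
        # each intercept by < ~0.04 log10, well under the 0.27 log10 gap,
        # so the noise-free ranking is exact
        ab = 2.0 ** np.linspace(-1.5, 1.5, 7)
        spots, _ = simulate_rppm_slide(SlideSimConfig(
            n_samples=7, noise_sigma=0.0, true_abundance=ab, seed=0))
        res = quantify_slide(spots)
        q = res.quantifications.set_index("sample_id")
        yint = np.array([q.loc[f"S{i:03d}", "y_intercept"] for i in range(7)])
        assert (np.diff(yint) > 0).all()
        assert spearmanr(np.log2(ab), yint).statistic == pytest.approx(1.0)

    def test_noisy_slide_rank_recovery(self, noise_free_slide):
        spots, truth, cfg = noise_free_slide
        res = quantify_slide(spots)
        q = res.quantifications.set_index("sample_id")
        yint = [q.loc[f"S{i:03d}", "y_intercept"] for i in range(16)]
        rho = spearmanr(np.log2(cfg.true_abundance), yint).statistic
        assert rho >= 0.95

    def test_group_summary_mean_sem(self):
        quant = pd.DataFrame({"sample_id": list("abcdef"),
                              "y_intercept": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        groups = {k: ("g1" if k in "abc" else "g2") for k in "abcdef"}
        out = summarize_groups(quant, groups).set_index("group")
        assert out.loc["g1", "mean"] == pytest.approx(2.0)
        assert out.loc["g1", "sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert out.loc["g1", "n"] == 3
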