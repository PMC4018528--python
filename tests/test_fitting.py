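"""Parameter-learning procedures: SSR objective, emetine fit, synthesis-rate
inference, grid searches and the KD-ratio equivalence scans."""

import itertools

import numpy as np
import pytest

from capinit import TABLE1_TOTALS
from capinit.fitting import (
    BoundaryWarning,
    GridPredictor,
    combined_factor_scan,
    enumerate_constrained_tuples,
    equivalence_scan,
    fit_klys_emetine,
    fit_rapamycin,
    grid_search_fertilization,
    infer_kcat_4ebp,
    kd_ratio_fold_of,
    predict_total_4ebp_pct,
    ssr,
)
from capinit.model import TimeCourse
from capinit.synthetic import (
    DEFAULT_SAMPLE_TIMES_MIN,
    gen_4ebp_timecourse,
    gen_emetine_decay,
)


def flat_course(value=100.0, times=(0, 10, 20, 30), n_rep=1):
    t = np.tile(times, n_rep).astype(float)
    reps = np.repeat([f"r{i}" for i in range(n_rep)], len(times))
    return TimeCourse(t, np.full(len(t), float(value)), reps)


class TestSSR:
    def test_perfect_prediction_gives_zero(self):
        tc = flat_course(100.0)
        assert ssr(tc, lambda t: np.full(len(t), 100.0)) == 0.0

    def test_unit_offsets_sum(self):
        tc = flat_course(101.0, times=tuple(range(10)))
        assert ssr(tc, lambda t: np.full(len(t), 100.0)) == pytest.approx(10.0)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            TimeCourse(np.array([]), np.array([]), np.array([]))

    def test_matches_noise_variance_expectation(self):
        """SSR/N against the true curve approaches the noise-model variance.

        The per-replicate t=0 renormalization zeroes the t=0 residual and
        adds correlated multiplicative noise, so the expectation is computed
        by a direct numpy Monte Carlo of the noise model, not sigma^2.
        """
        sigma, n_rep, seed = 5.0, 200, 11
        times = np.array(DEFAULT_SAMPLE_TIMES_MIN)
        truth = predict_total_4ebp_pct(
            times, {"k_off1": 8.0, "k_lys_4ebp": 32.5}, 5.0
        )
        tc = gen_4ebp_timecourse(
            "fertilization", noise_sd_pct=sigma, n_replicates=n_rep, seed=seed
        )
        observed = ssr(tc, lambda t: np.interp(t, times, truth)) / len(tc)

        rng = np.random.default_rng(12345)
        draws = truth[None, :] + rng.normal(0, sigma, size=(4000, len(times)))
        draws = 100.0 * draws / draws[:, [0]]
        per_point = np.mean((draws - truth[None, :]) ** 2, axis=0)
        expected = per_point.mean()
        se = np.std(np.mean((draws - truth[None, :]) ** 2, axis=1)) / np.sqrt(n_rep)
        assert abs(observed - expected) < 4 * se


class TestEmetineFit:
    def test_noiseless_recovery_is_essentially_exact(self):
        tc = gen_emetine_decay(noise_sd_pct=0.0, n_replicates=1, seed=0)
        fit = fit_klys_emetine(tc)
        assert fit.k_lys == pytest.approx(5.9e-4, rel=1e-3)
        assert not fit.at_bound

    def test_noisy_recovery_within_ten_percent(self):
        """Monte-Carlo recovery: 8 replicates at 5-point noise, 20 seeds."""
        errs = []
        for seed in range(20):
            tc = gen_emetine_decay(noise_sd_pct=5.0, n_replicates=8, seed=seed)
            fit = fit_klys_emetine(tc)
            errs.append(abs(fit.k_lys - 5.9e-4) / 5.9e-4)
        assert np.median(errs) < 0.10
        assert np.mean(np.array(errs) < 0.10) >= 0.8

    def test_flat_data_hits_lower_bound_with_warning(self):
        tc = flat_course(100.0, times=(0, 15, 30, 45, 60), n_rep=3)
        with pytest.warns(BoundaryWarning):
            fit = fit_klys_emetine(tc)
        assert fit.at_bound
        assert fit.k_lys == pytest.approx(1e-6, rel=0.05)


class TestInferKcat:
    def test_matches_published_synthesis_constant(self):
        assert infer_kcat_4ebp() == pytest.approx(3.2e-3, rel=0.05)

    def test_least_squares_and_closed_form_agree(self):
        ls = infer_kcat_4ebp(method="least_squares")
        cf = infer_kcat_4ebp(method="closed_form")
        assert abs(ls - cf) / cf < 0.01

    def test_no_degradation_needs_no_synthesis(self, rates):
        assert infer_kcat_4ebp(params=rates.replace(k_lys_4ebp=0.0)) == 0.0


class TestGridSearch:
    def test_noiseless_recovery_lands_on_generating_node(self, baseline):
        data = gen_4ebp_timecourse("fertilization", noise_sd_pct=0.0,
                                   n_replicates=1, seed=0)
        gp = GridPredictor(
            data.times_min, [4.0, 8.0, 16.0], [16.0, 32.5, 64.0],
            [3.0, 5.0, 8.0], TABLE1_TOTALS, baseline,
        )
        fit = gp.fit(data)
        assert (fit.fold_koff1, fit.fold_klys, fit.ramp_min) == (8.0, 32.5, 5.0)
        assert fit.ssr < 1e-6

    def test_single_parameter_search_fits_worse_than_joint(self, baseline):
        """Freezing the degradation axis at 1 cannot fit fertilization data
        as well as the two-parameter search."""
        data = gen_4ebp_timecourse("fertilization", noise_sd_pct=5.0,
                                   n_replicates=10, seed=5)
        axK = [1.0, 2.0, 4.0, 8.0, 16.0, 32.5, 64.0, 100.0]
        ramps = [1.0, 3.0, 5.0, 8.0, 15.0]
        joint = GridPredictor(data.times_min, axK, axK, ramps,
                              TABLE1_TOTALS, baseline).fit(data)
        koff1_only = GridPredictor(data.times_min, axK, [1.0], ramps,
                                   TABLE1_TOTALS, baseline).fit(data)
        assert joint.ssr < koff1_only.ssr

    def test_grid_refinement_never_increases_best_ssr(self, baseline):
        data = gen_4ebp_timecourse("fertilization", noise_sd_pct=5.0,
                                   n_replicates=4, seed=9)
        coarse_ax = [2.0, 8.0, 32.5]
        fine_ax = [2.0, 4.0, 8.0, 16.0, 32.5]
        coarse = GridPredictor(data.times_min, coarse_ax, coarse_ax, [5.0],
                               TABLE1_TOTALS, baseline).fit(data)
        fine = GridPredictor(data.times_min, fine_ax, fine_ax, [5.0],
                             TABLE1_TOTALS, baseline).fit(data)
        assert fine.ssr <= coarse.ssr

    def test_ssr_invariant_to_replicate_relabelling(self, baseline):
        data = gen_4ebp_timecourse("fertilization", noise_sd_pct=5.0,
                                   n_replicates=4, seed=2)
        gp = GridPredictor(data.times_min, [8.0], [32.5], [5.0],
                           TABLE1_TOTALS, baseline)
        a = gp.fit(data).ssr
        # permute observation order (replicates interleaved)
        order = np.argsort(data.times_min, kind="stable")
        shuffled = TimeCourse(
            data.times_min[order], data.values[order], data.replicates[order]
        )
        assert gp.fit(shuffled).ssr == pytest.approx(a)

    def test_rapamycin_noiseless_recovery(self, baseline):
        data = gen_4ebp_timecourse("rapamycin", noise_sd_pct=0.0,
                                   n_replicates=1, seed=0)
        gp = GridPredictor(
            data.times_min, [1.0, 2.0, 8.0], [8.0, 16.0, 32.5],
            [10.0, 33.0, 66.0], TABLE1_TOTALS, baseline,
        )
        fit = gp.fit(data)
        assert (fit.fold_koff1, fit.fold_klys, fit.ramp_min) == (1.0, 16.0, 33.0)

    def test_slower_ramp_delays_4ebp_decay(self):
        """At fixed folds a 33-min ramp leaves more 4E-BP at 15 min than a
        5-min ramp (monotone ramp effect)."""
        times = np.array([15.0])
        folds = {"k_lys_4ebp": 16.0}
        slow = predict_total_4ebp_pct(times, folds, 33.0)
        fast = predict_total_4ebp_pct(times, folds, 5.0)
        assert slow[0] > fast[0]


class TestEquivalenceScan:
    def test_all_routes_shift_kd_ratio_eightfold(self, baseline):
        for which, fold in [("k_off1", 8.0), ("k_on2", 8.0),
                            ("k_on1", 1 / 8), ("k_off2", 1 / 8)]:
            p = baseline.scaled({which: fold})
            ratio = (p.kd1 / p.kd2) / (baseline.kd1 / baseline.kd2)
            assert ratio == pytest.approx(8.0, rel=1e-12)

    def test_koff1_mechanism_identified_on_koff1_data(self):
        data = gen_4ebp_timecourse("fertilization", noise_sd_pct=5.0,
                                   n_replicates=10, seed=3)
        res = equivalence_scan(data)
        assert min(res, key=res.get) == "k_off1"

    def test_null_scan_on_null_data_is_exactly_degenerate(self):
        """With no perturbation in either data or scan, the four routes
        coincide and their SSRs are identical."""
        null = gen_4ebp_timecourse("unfertilized", noise_sd_pct=5.0,
                                   n_replicates=5, seed=7)
        res = equivalence_scan(null, fold_klys_fixed=1.0, kd_ratio_fold=1.0)
        vals = list(res.values())
        assert all(v == pytest.approx(vals[0], rel=1e-9) for v in vals)

    def test_no_route_fits_null_data(self):
        """Fertilization-scale perturbations badly misfit unperturbed data."""
        null = gen_4ebp_timecourse("unfertilized", noise_sd_pct=5.0,
                                   n_replicates=5, seed=7)
        res = equivalence_scan(null)
        n_obs = 5 * len(DEFAULT_SAMPLE_TIMES_MIN)
        assert min(res.values()) > 100 * n_obs  # >> noise floor (~25 per point)


class TestCombinedFactorScan:
    def test_enumeration_count_matches_bruteforce_oracle(self):
        """Power-of-2 exponents in {-5..5}^4 with the x8 KD-ratio constraint:
        count independently by exhaustive enumeration of exponent sums."""
        count = 0
        for a, b, c, d in itertools.product(range(-5, 6), repeat=4):
            if a - b + c - d == 3:
                count += 1
        tuples = enumerate_constrained_tuples()
        assert len(tuples) == count == 804

    def test_every_tuple_satisfies_constraint_exactly(self):
        for t in enumerate_constrained_tuples():
            assert kd_ratio_fold_of(t) == pytest.approx(8.0, rel=1e-12)

    def test_koff1_only_tuple_is_optimal_on_koff1_data(self):
        """On noiseless data generated by the k_off1 mechanism the pure
        (x8, x1, x1, x1) tuple fits perfectly; every other constrained tuple
        is kinetically distinguishable and fits worse."""
        data = gen_4ebp_timecourse("fertilization", noise_sd_pct=0.0,
                                   n_replicates=1, seed=3)
        tuples_df, summary_df = combined_factor_scan(
            data, exponents=range(-2, 4)
        )
        best = tuples_df.loc[tuples_df["ssr"].idxmin()]
        assert (
            best["fold_koff1"], best["fold_kon1"],
            best["fold_kon2"], best["fold_koff2"],
        ) == (8.0, 1.0, 1.0, 1.0)
        assert best["ssr"] < 1e-6
        # summary aggregates: mean over tuples sharing each single-param fold
        g = summary_df[summary_df["parameter"] == "koff1"]
        assert g["count"].sum() == len(tuples_df)
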