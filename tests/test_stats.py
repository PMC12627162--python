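"""Transfer-statistics tests: shifts, tests, PSE, maps, binning, models."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from gazebias.observer import LandmarkDesign, simulate_landmark_session
from gazebias.stats import (
    ShiftMeasure,
    alignment_test,
    barycenter,
    bin_gaze_target_distance,
    combine_maps_median,
    congruent_bias,
    early_window_shift,
    fit_learning_model,
    fit_psychometric,
    fixation_density_map,
    image_shift_collapse,
    ols_regression,
    one_sample_t_one_sided,
    signed_shift,
    standardize,
)
from gazebias.task_engine import GazeTrace, StudyConfig, TargetSpec, \
    TrialRecord


def _fix(rows):
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "x", "y",
                                       "duration_s"])


class TestShifts:
    def test_barycenter_balances_and_mirrors(self):
        fx = _fix([(0, 1, -2.0, 0, 1), (1, 2, 2.0, 0, 1)])
        assert barycenter(fx) == 0.0
        single = _fix([(0, 1, 3.0, 0, 1)])
        assert barycenter(single) == 3.0
        mirrored = single.assign(x=-single["x"])
        assert barycenter(mirrored) == -3.0

    def test_barycenter_empty_is_nan(self):
        assert math.isnan(barycenter(_fix([])))

    def test_signed_shift_collapses_groups(self):
        m = ShiftMeasure(1, "BSV", 0.0, -0.5, "left")
        assert m.raw_shift == -0.5
        assert m.signed_shift == 0.5
        assert signed_shift(-0.5, "right") == -0.5

    def test_sign_correction_equivariance(self, rng):
        """Negating x and swapping groups leaves signed shifts identical."""
        raws = rng.normal(0.2, 1.0, 40)
        sides = np.where(rng.random(40) < 0.5, "left", "right")
        flipped_sides = np.where(sides == "left", "right", "left")
        a = [signed_shift(r, s) for r, s in zip(raws, sides)]
        b = [signed_shift(-r, s) for r, s in zip(raws, flipped_sides)]
        np.testing.assert_allclose(a, b)

    def test_median_collapse(self):
        assert image_shift_collapse([1.0, 2.0, 3.0]) == 2.0
        assert image_shift_collapse([0.0] * 29 + [10.0]) == 0.0

    def test_median_minimizes_l1(self, rng):
        vals = rng.normal(0, 2, 31)
        med = image_shift_collapse(vals)
        grid = np.linspace(vals.min(), vals.max(), 400)
        l1 = np.abs(vals[None, :] - grid[:, None]).sum(axis=1)
        assert np.abs(vals - med).sum() <= l1.min() + 1e-9


class TestOneSidedT:
    def test_printed_summary_worked_example(self):
        # group shift summary M=0.49 deg, SD=1.61, n=40; two-point sample
        # with exact sample (ddof=1) standard deviation 1.61
        dev = 1.61 * math.sqrt(39 / 40)
        x = np.array([0.49 - dev, 0.49 + dev] * 20)
        res = one_sample_t_one_sided(x)
        assert res["t"] == pytest.approx(0.49 / (1.61 / math.sqrt(40)),
                                         rel=1e-3)
        assert res["t"] == pytest.approx(1.92, abs=0.01)
        assert res["cohens_d"] == pytest.approx(0.30, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_one_sided(np.zeros(10))

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            res = one_sample_t_one_sided(rng.normal(0, 1, 40))
            rejections += res["p"] < 0.05
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert rejections / n_sim == pytest.approx(0.05, abs=3 * se)

    def test_direction_less(self):
        res = one_sample_t_one_sided([-1.0, -2.0, -1.5], direction="less")
        assert res["p"] < 0.05


class TestPsychometric:
    def test_symmetric_coinflips_give_zero_pse(self):
        offsets = np.tile([-0.4, -0.2, 0.2, 0.4], 10)
        resp = np.tile([0, 1], 20)  # exactly half right everywhere
        fit = fit_psychometric(offsets, resp)
        assert fit.pse == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_over_replicates(self):
        rng = np.random.default_rng(11)
        pses = []
        for _ in range(200):
            df = simulate_landmark_session(0.2, 10.0, LandmarkDesign(), rng)
            fit = fit_psychometric(df["offset_deg"], df["resp_right"])
            if fit.converged:
                pses.append(fit.pse)
        mean_pse = np.mean(pses)
        se = np.std(pses) / math.sqrt(len(pses))
        assert abs(mean_pse - 0.2) < max(3 * se, 0.02)

    def test_label_flip_symmetry(self, rng):
        df = simulate_landmark_session(0.15, 8.0, rng=rng)
        fit = fit_psychometric(df["offset_deg"], df["resp_right"])
        fit_m = fit_psychometric(-df["offset_deg"], 1 - df["resp_right"])
        assert fit_m.pse == pytest.approx(-fit.pse, abs=1e-6)

    def test_complete_separation_flagged(self):
        offsets = np.repeat([-0.6, -0.2, 0.2, 0.6], 5)
        resp = (offsets > 0).astype(int)
        fit = fit_psychometric(offsets, resp)
        assert not fit.converged
        assert fit.pse == pytest.approx(0.0)


class TestExploratoryIndices:
    def test_congruent_bias_sign_rule(self):
        assert congruent_bias([-1.5], "left") == 1.5
        assert congruent_bias([-1.5], "right") == -1.5
        assert congruent_bias([0.0], "left") == 0.0
        assert math.isnan(congruent_bias([], "left"))

    def test_early_window_shift(self):
        sacc = pd.DataFrame({"onset_s": [0.3, 1.2]})
        assert early_window_shift(sacc, [4.0, -8.0]) == 4.0
        late = pd.DataFrame({"onset_s": [1.2]})
        assert math.isnan(early_window_shift(late, [-8.0]))


class TestDensityMaps:
    def test_single_fixation_peaks_at_center(self):
        fx = _fix([(1.0, 2.0, 0.0, 0.0, 1.0)])
        m = fixation_density_map(fx)
        assert m.grid.sum() == pytest.approx(1.0, abs=1e-9)
        iy, ix = np.unravel_index(np.argmax(m.grid), m.grid.shape)
        assert abs(m.x_centers[ix]) < 0.3
        assert abs(m.y_centers[iy]) < 0.3

    def test_initial_window_excluded(self):
        fx = _fix([(0.1, 0.5, 10.0, 0.0, 0.4), (1.0, 2.0, -5.0, 0.0, 1.0)])
        m = fixation_density_map(fx)
        iy, ix = np.unravel_index(np.argmax(m.grid), m.grid.shape)
        assert m.x_centers[ix] == pytest.approx(-5.0, abs=0.3)

    def test_mirror_symmetric_input_gives_symmetric_map(self):
        fx = _fix([(1, 2, -4.0, 1.0, 1.0), (2, 3, 4.0, 1.0, 1.0)])
        m = fixation_density_map(fx)
        np.testing.assert_allclose(m.grid, m.grid[:, ::-1], atol=1e-12)

    def test_flip_pools_left_group_onto_right(self):
        fx = _fix([(1, 2, -6.0, 0.0, 1.0)])
        m = fixation_density_map(fx, flip_x=True)
        assert m.mass_right_of_midline() > 0.9

    def test_median_combination_normalized(self, rng):
        maps = []
        for _ in range(6):
            fx = _fix([(1, 2, rng.normal(3, 2), rng.normal(0, 2), 1.0)])
            maps.append(fixation_density_map(fx))
        combined = combine_maps_median(maps)
        assert combined.grid.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(combined.grid >= 0)

    def test_empty_input_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            m = fixation_density_map(_fix([]))
        assert m.grid.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(m.grid, m.grid.flat[0])


class TestAlignment:
    def test_null_generator_long_run_proportion(self):
        rng = np.random.default_rng(6)
        n = 100000
        sides = np.where(rng.random(n) < 0.5, "left", "right")
        ivt = np.where(rng.random(n) < 0.5, "left", "right")
        bsv = np.where(rng.random(n) < 0.5, "left", "right")
        res = alignment_test(sides, ivt, bsv)
        se = math.sqrt(0.25 * 0.75 / n)
        assert res["proportion"] == pytest.approx(0.25, abs=3 * se)

    def test_exact_tail_at_printed_counts(self):
        # oracle: direct binomial tail sum at k=18 of n=40, p0=0.25
        expect = sum(math.comb(40, j) * 0.25**j * 0.75**(40 - j)
                     for j in range(18, 41))
        sides = ["right"] * 40
        ivt = ["right"] * 18 + ["left"] * 22
        bsv = ["right"] * 18 + ["right"] * 22
        res = alignment_test(sides, ivt, bsv)
        assert res["k"] == 18 and res["n"] == 40
        assert res["proportion"] == pytest.approx(0.45)
        assert res["p"] == pytest.approx(expect, rel=1e-10)
        assert res["p"] == pytest.approx(0.0047, abs=5e-4)

    def test_all_aligned_closed_form(self):
        res = alignment_test(["left"] * 5, ["left"] * 5, ["left"] * 5)
        assert res["p"] == pytest.approx(0.25**5, rel=1e-9)

    def test_missing_directions_excluded(self):
        res = alignment_test(["left", "right"], ["left", None],
                             ["left", "right"])
        assert res["n"] == 1 and res["n_excluded"] == 1


def _trial_from_distance(dist_fn, duration_s=2.0, fs=100.0):
    """TrialRecord whose gaze runs along +x with a given distance profile."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    d = np.array([dist_fn(ti) for ti in t])
    trace = GazeTrace(t, d, np.zeros(n), fs=fs)
    return TrialRecord(target=TargetSpec(0.0, 0.0), trace=trace,
                       volume_series=np.zeros(n), found=False,
                       search_time_s=duration_s, trial_number=1,
                       bias_label="biased")


class TestBinning:
    def test_constant_distance(self):
        binned = bin_gaze_target_distance(_trial_from_distance(lambda t: 5.0))
        assert len(binned) == 4
        np.testing.assert_allclose(binned["median_distance_deg"], 5.0)
        np.testing.assert_allclose(binned["time_bin_center_s"],
                                   [0.25, 0.75, 1.25, 1.75])

    def test_linear_descent_medians_are_midpoints(self):
        trial = _trial_from_distance(lambda t: 10.0 * (1.0 - t),
                                     duration_s=1.0)
        binned = bin_gaze_target_distance(trial)
        np.testing.assert_allclose(binned["median_distance_deg"],
                                   [7.5, 2.5], atol=0.1)

    def test_no_bins_beyond_trial_end(self):
        trial = _trial_from_distance(lambda t: 3.0, duration_s=1.2)
        binned = bin_gaze_target_distance(trial)
        assert binned["time_bin_center_s"].max() <= 1.5

    def test_carry_forward_padding_for_plots(self):
        trial = _trial_from_distance(lambda t: 3.0, duration_s=1.2)
        binned = bin_gaze_target_distance(trial, pad_to_deadline=True)
        assert binned["time_bin_center_s"].max() == pytest.approx(9.75)
        assert binned["median_distance_deg"].iloc[-1] == pytest.approx(3.0)


class TestStandardize:
    def test_closed_form(self):
        np.testing.assert_allclose(standardize([1.0, 2.0, 3.0]),
                                   [-1.0, 0.0, 1.0])
        z = standardize(np.arange(10.0))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        v = rng.normal(3, 2, 50)
        np.testing.assert_allclose(standardize(v), standardize(5 * v - 7))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0])


def _simulate_binned(rng, n_participants=10, n_trials=60, beta_time=-0.2,
                     beta_trial=0.0, shape=8.0):
    """Generative recipe: distance = exp(b0 + b·z) * gamma noise."""
    rows = []
    times = np.arange(0.25, 10.0, 0.5)
    # population (ddof=0) scaling: matches the row-level standardization the
    # model applies, since every time/trial value repeats uniformly
    z_time = (times - times.mean()) / times.std()
    for pid in range(n_participants):
        trials = np.arange(1, n_trials + 1)
        z_trial = (trials - trials.mean()) / trials.std()
        for i, trial in enumerate(trials):
            mu = np.exp(2.0 + beta_time * z_time + beta_trial * z_trial[i])
            y = rng.gamma(shape, mu / shape)
            rows.append(pd.DataFrame({
                "pid": pid, "trial_number": trial,
                "bias_label": "biased" if i % 2 == 0 else "unbiased",
                "time_bin_center_s": times, "median_distance_deg": y}))
    return pd.concat(rows, ignore_index=True)


class TestLearningModel:
    def test_recovers_known_time_factor(self):
        rng = np.random.default_rng(31)
        binned = _simulate_binned(rng, n_participants=8, n_trials=40)
        table = fit_learning_model(binned, lrt=False)
        assert table.loc["time_z", "factor"] == pytest.approx(
            math.exp(-0.2), abs=0.01)

    def test_identical_streams_give_unit_bias_factor(self):
        rng = np.random.default_rng(32)
        binned = _simulate_binned(rng, n_participants=6, n_trials=30)
        # rebuild so biased/unbiased rows are exact copies of each other
        biased = binned[binned["bias_label"] == "biased"]
        mirror = biased.assign(bias_label="unbiased")
        table = fit_learning_model(pd.concat([biased, mirror]), lrt=False)
        assert table.loc["bias", "factor"] == pytest.approx(1.0, abs=1e-6)

    def test_lrt_type_i_error(self):
        rng = np.random.default_rng(33)
        rejections = 0
        n_sim = 120
        for _ in range(n_sim):
            binned = _simulate_binned(rng, n_participants=2, n_trials=10,
                                      beta_time=0.0)
            table = fit_learning_model(binned)
            rejections += table.loc["time_z", "p"] < 0.05
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert rejections / n_sim == pytest.approx(0.05, abs=max(3 * se, 0.04))

    def test_nonpositive_distance_rejected(self, rng):
        binned = _simulate_binned(rng, n_participants=2, n_trials=5)
        binned.loc[0, "median_distance_deg"] = 0.0
        with pytest.raises(ValueError):
            fit_learning_model(binned)


class TestOls:
    def test_exact_fit(self):
        x = np.arange(10.0)
        table = ols_regression(2.0 * x, pd.DataFrame({"x": x}))
        assert table.loc["x", "estimate"] == pytest.approx(2.0)
        assert table.loc["const", "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_row_permutation_invariance(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 30),
                          "b": rng.normal(0, 1, 30)})
        y = 1.0 + 0.5 * X["a"] - 0.2 * X["b"] + rng.normal(0, 0.1, 30)
        t1 = ols_regression(y, X)
        perm = rng.permutation(30)
        t2 = ols_regression(y.to_numpy()[perm], X.iloc[perm])
        np.testing.assert_allclose(t1["estimate"], t2["estimate"])

    def test_negative_moderator_recovered_with_power(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(60):
            cb = rng.normal(0, 1.0, 40)
            y = -0.5 * cb + rng.normal(0, 0.8, 40)
            table = ols_regression(y, pd.DataFrame({"congruent_bias": cb}))
            hits += (table.loc["congruent_bias", "estimate"] < 0
                     and table.loc["congruent_bias", "p"] < 0.05)
        assert hits / 60 > 0.8

    def test_rank_deficiency_reported(self, rng):
        a = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="collinear"):
            ols_regression(rng.normal(0, 1, 20), X)
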