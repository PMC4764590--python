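import numpy as np
import pytest

import untwist as ut
from untwist.io import ConfigurationError
from untwist.trajectories import (MODEL_FAMILIES, align_and_average,
                                  clean_trajectory, compute_shift,
                                  fit_composite, fit_growth,
                                  neighbor_differences, select_model, smooth50)


class TestCleanTrajectory:
    def test_spike_replaced_by_neighbor_mean(self):
        s = 20 + 5 * np.sin(np.arange(50) * 0.1)
        s[25] += 50.0
        c = clean_trajectory(s)
        assert c[25] == pytest.approx((s[24] + s[26]) / 2, abs=0.5)
        # only the spike's immediate neighbourhood may be touched, and only
        # slightly (their rolling-median windows contain the spike)
        changed = np.nonzero(~np.isclose(c, s))[0]
        assert set(changed) <= {23, 24, 25, 26, 27}
        truth = 20 + 5 * np.sin(np.arange(50) * 0.1)
        assert np.max(np.abs(np.delete(c - truth, 25))) < 0.6

    def test_gap_filled_linearly(self):
        c = clean_trajectory(np.array([10.0, np.nan, np.nan, 16.0]))
        np.testing.assert_allclose(c, [10, 12, 14, 16])

    def test_clean_series_unchanged(self):
        s = np.linspace(0, 10, 40) ** 1.5
        np.testing.assert_allclose(clean_trajectory(s), s)

    def test_manual_marks_take_precedence(self):
        s = np.arange(10.0)
        c = clean_trajectory(s, manual_marks=[5])
        assert c[5] == pytest.approx(5.0)           # interpolated back onto line

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            clean_trajectory(np.full(5, np.nan))


class TestFitGrowth:
    def test_noiseless_logistic_recovered_to_4_digits(self):
        t = np.arange(100) * 2.5
        y = 160.0 / (1 + np.exp(-0.08 * (t - 100.0)))
        fr = fit_growth(y, t, "logistic3")
        assert fr.converged
        assert fr.params["A"] == pytest.approx(160.0, rel=1e-4)
        assert fr.params["B"] == pytest.approx(0.08, rel=1e-4)
        assert fr.params["C"] == pytest.approx(100.0, rel=1e-4)

    def test_logistic_value_at_inflection_is_half_asymptote(self):
        f, names, _ = MODEL_FAMILIES["logistic3"]
        assert f(np.array([100.0]), 160.0, 0.08, 100.0)[0] == pytest.approx(80.0)

    def test_constant_series_linear_fit(self):
        t = np.arange(10.0)
        fr = fit_growth(np.full(10, 7.0), t, "linear")
        assert fr.params["p1"] == pytest.approx(0.0, abs=1e-12)
        assert fr.params["p2"] == pytest.approx(7.0)
        assert fr.ssr == pytest.approx(0.0, abs=1e-18)

    def test_information_criteria_definitions(self):
        t = np.arange(30.0)
        fr = fit_growth(2 * t + 1 + np.sin(t), t, "linear")
        n, k = fr.n, 2
        assert fr.aic == pytest.approx(n * np.log(fr.ssr / n) + 2 * k)
        assert fr.sc == pytest.approx(n * np.log(fr.ssr / n) + k * np.log(n))

    @pytest.mark.parametrize("fam,params", [
        ("gompertz3", (150.0, 0.05, 80.0)),
        ("vonBertalanffy", (150.0, 0.02, -10.0)),
        ("exponential3", (150.0, 20.0, 0.02)),
        ("logistic4", (150.0, 10.0, 100.0, 12.0)),
        ("mmf4", (150.0, 10.0, 0.01, 2.0)),
        ("power", (2.0, 0.7, 5.0)),
    ])
    def test_each_family_fits_its_own_noiseless_data(self, fam, params):
        t = np.linspace(1, 250, 100)
        f, names, _ = MODEL_FAMILIES[fam]
        y = f(t, *params)
        fr = fit_growth(y, t, fam)
        assert fr.ssr < 1e-6 * np.sum(y ** 2)

    def test_nonconvergence_is_flagged_not_raised(self):
        t = np.arange(5.0)
        fr = fit_growth(np.array([1, -1, 1, -1, 1.0]), t, "mmf4")
        assert isinstance(fr.converged, bool)      # never raises


class TestSelectModel:
    def test_logistic_data_prefers_logistic(self):
        rng = np.random.default_rng(0)
        t = np.arange(100) * 2.5
        y = 160.0 / (1 + np.exp(-0.08 * (t - 100.0)))
        fits = select_model(y, t, ["logistic3", "gompertz3", "vonBertalanffy",
                                   "exponential3"])
        assert fits[0].model_kind == "logistic3"

    def test_linear_data_beats_poly4_by_sc(self):
        rng = np.random.default_rng(1)
        t = np.arange(80.0)
        y = 3 * t + 2 + rng.normal(0, 1.0, 80)
        fits = {f.model_kind: f for f in select_model(y, t, ["linear", "poly4"])}
        assert fits["linear"].sc < fits["poly4"].sc

    def test_single_candidate_returned_first(self):
        t = np.arange(10.0)
        fits = select_model(2 * t, t, ["linear"])
        assert len(fits) == 1 and fits[0].model_kind == "linear"


class TestComputeShift:
    def test_worked_inflection_example(self):
        """Inflection points 42.6 and 37.7 timepoints: shift right by 5."""
        a = ut.FitResult("logistic3", {"A": 1, "B": 1, "C": 42.6}, 0, 0, 0, 10)
        b = ut.FitResult("logistic3", {"A": 1, "B": 1, "C": 37.7}, 0, 0, 0, 10)
        assert compute_shift(a, b, 1.0) == 5

    def test_identical_fits_zero_shift(self):
        a = ut.FitResult("logistic3", {"C": 50.0}, 0, 0, 0, 10)
        assert compute_shift(a, a, 2.5) == 0

    def test_negative_shift_rounds_away_from_half(self):
        a = ut.FitResult("logistic3", {"C": 10.0}, 0, 0, 0, 10)
        b = ut.FitResult("logistic3", {"C": 12.4}, 0, 0, 0, 10)
        assert compute_shift(a, b, 1.0) == -2

    def test_missing_inflection_raises(self):
        a = ut.FitResult("linear", {"p1": 1, "p2": 0}, 0, 0, 0, 10)
        with pytest.raises(ValueError):
            compute_shift(a, a, 1.0)


class TestAlignAndAverage:
    def test_preshifted_identical_embryos_overlap_exactly(self):
        tt, _ = ut.make_trajectory_set(n_embryos=2, true_shifts=[0, 3],
                                       dt=2.5, noise_sd=0.0, seed=0)
        res = align_and_average(tt, reference_embryo=0, clean=False)
        both = res.averaged.dropna(subset=["sd_Z"])
        inner = both[both["n"] == 2]
        assert np.nanmax(inner["sd_Z"]) < 1e-6

    def test_known_shifts_recovered_exactly(self):
        tt, truth = ut.make_trajectory_set(n_embryos=5,
                                           true_shifts=[0, 2, 4, -1, 5],
                                           dt=2.5, noise_sd=2.0, seed=7)
        res = align_and_average(tt, reference_embryo=0)
        by_emb = {}
        for (e, c), s in res.shifts.items():
            by_emb.setdefault(e, []).append(s)
        rec = [int(np.median(v)) for _, v in sorted(by_emb.items())]
        assert rec == truth.true_shifts

    def test_coarse_embryo_resampled_to_reference_grid(self):
        tt, _ = ut.make_trajectory_set(n_embryos=2, true_shifts=[0, 2],
                                       dt=[2.5, 5.0], noise_sd=0.0, seed=3)
        res = align_and_average(tt, reference_embryo=0, clean=False)
        assert res.dt_ref == 2.5
        spacing = np.diff(np.unique(res.aligned.data["time_min"]))
        np.testing.assert_allclose(spacing, 2.5)

    def test_averaging_reduces_noise_by_sqrt_n(self):
        tt, _ = ut.make_trajectory_set(n_embryos=5, true_shifts=[0] * 5,
                                       dt=2.5, noise_sd=2.0, seed=11)
        res = align_and_average(tt, reference_embryo=0, clean=False)
        sd = res.averaged.loc[res.averaged["n"] == 5, "sd_Z"]
        # per-timepoint sample SD across embryos estimates sigma; the SEM of
        # the 5-embryo average is then sigma/sqrt(5)
        assert np.nanmean(sd) / np.sqrt(5) == pytest.approx(2.0 / np.sqrt(5),
                                                            rel=0.2)


@pytest.fixture(scope="module")
def composite():
    tt, truth = ut.make_trajectory_set(n_embryos=5, true_shifts=[0, 2, 4, -1, 5],
                                       dt=2.5, noise_sd=1.0, seed=2)
    res = align_and_average(tt, reference_embryo=0)
    return fit_composite(res.averaged, res.shifts), truth


class TestFitComposite:

    def test_seam_cells_get_table_families(self, composite):
        comp, _ = composite
        assert comp.fits["H0"]["X"].model_kind == "power"
        assert comp.fits["H0"]["Y"].model_kind == "linear"
        assert comp.fits["H0"]["Z"].model_kind == "logistic3"

    def test_fitted_asymptote_matches_generator(self, composite):
        comp, truth = composite
        for cell in ("H0", "T"):
            A_true = truth.cells[cell]["Z"][1]["A"]
            assert comp.fits[cell]["Z"].params["A"] == pytest.approx(A_true,
                                                                     rel=0.05)

    def test_residual_stats_zero_for_self_fit(self):
        import pandas as pd
        t = np.arange(60) * 2.5
        df = pd.DataFrame({"cell": "ALA", "time_min": t,
                           "X": 2 * t + 1, "Y": 0.5 * t, "Z":
                           30 / (1 + np.exp(-0.1 * (t - 75)))})
        comp = fit_composite(df)
        mu = comp.residual_stats.set_index(["cell", "coord"])["mu_avg_fit"]
        assert mu[("ALA", "X")] == pytest.approx(0.0, abs=1e-8)

    def test_unknown_cell_type_is_configuration_error(self):
        import pandas as pd
        df = pd.DataFrame({"cell": "mystery9", "time_min": [0.0, 1, 2],
                           "X": [0.0] * 3, "Y": [0.0] * 3, "Z": [0.0] * 3})
        with pytest.raises(ConfigurationError, match="mystery9"):
            fit_composite(df)

    def test_can_smoothing_preserves_grid_length(self):
        import pandas as pd
        t = np.arange(80) * 2.5
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"cell": "CANR", "time_min": t,
                           "X": 10 - 0.02 * t + rng.normal(0, 0.3, 80),
                           "Y": np.full(80, 2.0),
                           "Z": 100 / (1 + np.exp(-0.08 * (t - 100)))})
        comp = fit_composite(df)
        assert len(comp.fitted) == 80
        assert np.isfinite(comp.fitted["Xfit"]).all()


class TestSmooth50:
    def test_linear_input_reproduced_exactly(self):
        y = 2.0 * np.arange(120) + 3.0
        np.testing.assert_allclose(smooth50(y), y, atol=1e-9)

    def test_step_input_becomes_monotone(self):
        y = np.concatenate([np.zeros(60), np.ones(60)])
        s = smooth50(y)
        assert np.all(np.diff(s) > -1e-9)

    def test_short_input_fully_defined(self):
        s = smooth50(np.arange(10.0))
        assert len(s) == 10 and np.isfinite(s).all()


class TestNeighborDifferences:
    @staticmethod
    def _composite_from(cells, noise=0.0, seed=0):
        tt, _ = ut.make_trajectory_set(n_embryos=2, cells=cells,
                                       true_shifts=[0, 0], dt=2.5,
                                       noise_sd=noise, seed=seed)
        res = align_and_average(tt, reference_embryo=0, clean=False)
        return fit_composite(res.averaged, res.shifts)

    def test_uniform_scaling_scales_all_separations(self):
        # homogeneity: doubling all asymptotes doubles the final separations
        from untwist.synthetic import default_cell_models
        base = default_cell_models()
        doubled = {c: {k: (fam, {**p, "A": 2 * p["A"]} if "A" in p else dict(p))
                       for k, (fam, p) in spec.items()}
                   for c, spec in base.items()}
        nd1 = neighbor_differences(self._composite_from(base))
        nd2 = neighbor_differences(self._composite_from(doubled))
        last1 = nd1.groupby("pair")["separation"].last()
        last2 = nd2.groupby("pair")["separation"].last()
        np.testing.assert_allclose(last2 / last1, 2.0, rtol=0.02)

    def test_origin_h0_growth_and_static_tail_recovered(self):
        """Origin→H0 grows from ~2.4 to ~23.8 µm while V6→T stays constant."""
        from untwist.synthetic import default_cell_models
        cells = default_cell_models()
        # V6 and T finished elongating before recording began (saturated
        # logistics): their separation stays essentially constant at 22.5 µm
        cells["V6"]["Z"] = ("logistic3", {"A": 120.0, "B": 0.08, "C": -60.0})
        cells["T"]["Z"] = ("logistic3", {"A": 142.5, "B": 0.08, "C": -60.0})
        # origin→H0 grows 2.4 → 23.8 µm over the recording
        cells["H0"]["Z"] = ("logistic3", {"A": 23.8, "B": 0.08, "C": 27.5})
        comp = self._composite_from(cells)
        nd = neighbor_differences(comp)
        changes = nd.groupby("pair")["start_to_end_change"].first()
        sep_h0 = nd[nd["pair"] == "origin-H0"]["separation"]
        assert sep_h0.iloc[-1] == pytest.approx(23.8, rel=0.05)
        assert changes["origin-H0"] == pytest.approx(23.8 - 2.4, abs=2.0)
        assert abs(changes["V6-T"]) < 1.0               # essentially constant

    def test_missing_seam_cell_named_in_error(self):
        from untwist.synthetic import default_cell_models
        cells = default_cell_models()
        del cells["V4"]
        comp = self._composite_from(cells)
        with pytest.raises(ValueError, match="V4"):
            neighbor_differences(comp)
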