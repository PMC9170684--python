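"""Spatiotemporal model fits, cutoffs, speed, API, elongation and OSI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import spearmanr

from vistreams import tuning
from vistreams.stimuli import SF_CENTERS_SFTF, TF_CENTERS_SFTF
from vistreams.tuning import (
    SpatioTemporalFit,
    anisotropy_preference_index,
    api_category,
    elongation_tuning_curve,
    fit_spatiotemporal,
    frequency_cutoffs,
    orientation_selectivity_index,
    orientation_time_course,
    peak_speed,
    select_best_fit,
    spatiotemporal_response,
    speed_flag,
    validate_osi,
)


def _grid_amps(A=1.0, sf0=0.08, tf0=2.0, ssf=1.0, stf=1.0, xi=0.0):
    sf = np.asarray(SF_CENTERS_SFTF)[:, None]
    tf = np.asarray(TF_CENTERS_SFTF)[None, :]
    return spatiotemporal_response(sf, tf, A, sf0, tf0, ssf, stf, xi)


def _fit(**kw):
    defaults = dict(A=1.0, sf0=0.08, tf0=2.0, sigma_sf=1.0, sigma_tf=1.0,
                    xi=0.0, nrmse=0.0)
    defaults.update(kw)
    return SpatioTemporalFit(**defaults)


class TestModelEvaluation:
    def test_peak_identity(self):
        f = _fit()
        assert f.evaluate(0.08, 2.0) == pytest.approx(1.0)

    def test_one_octave_off_peak(self):
        f = _fit()
        assert f.evaluate(0.16, 2.0) == pytest.approx(np.exp(-0.5))

    def test_slant_symmetry_of_temporal_factor(self):
        """With xi = 1, the TF factor is constant along tf ~ sf: moving
        one octave up in both SF and TF only pays the SF-Gaussian cost."""
        f = _fit(xi=1.0, sigma_sf=1.3, sigma_tf=0.7)
        ratio = f.evaluate(0.16, 4.0) / f.evaluate(0.08, 2.0)
        assert ratio == pytest.approx(np.exp(-0.5 / 1.3**2))


class TestFitSpatiotemporal:
    @pytest.mark.parametrize("params", [
        dict(A=1.0, sf0=0.08, tf0=2.0, ssf=1.0, stf=1.0, xi=0.0),
        dict(A=0.6, sf0=0.05, tf0=4.0, ssf=1.5, stf=0.8, xi=1.0),
        dict(A=2.0, sf0=0.12, tf0=1.0, ssf=0.8, stf=2.0, xi=-0.5),
    ])
    def test_noiseless_recovery(self, params):
        fit = fit_spatiotemporal(_grid_amps(**params))
        assert fit.nrmse < 1e-3
        assert fit.A == pytest.approx(params["A"], rel=0.01)
        assert fit.sf0 == pytest.approx(params["sf0"], rel=0.01)
        assert fit.tf0 == pytest.approx(params["tf0"], rel=0.01)
        assert fit.xi == pytest.approx(params["xi"], abs=0.01)

    def test_noisy_recovery_of_speed_index(self, rng):
        """xi = 1 with 5% additive noise: median recovery within stated tolerances."""
        errs_xi, errs_sf, errs_tf = [], [], []
        for _ in range(60):
            amps = _grid_amps(xi=1.0) + rng.normal(0.0, 0.05, (5, 6))
            fit = fit_spatiotemporal(amps)
            errs_xi.append(abs(fit.xi - 1.0))
            errs_sf.append(abs(np.log2(fit.sf0 / 0.08)))
            errs_tf.append(abs(np.log2(fit.tf0 / 2.0)))
        assert np.median(errs_xi) <= 0.15
        assert np.median(errs_sf) <= 0.25
        assert np.median(errs_tf) <= 0.25

    def test_optimizer_matches_bruteforce_grid_search(self):
        """The least-squares solution beats every coarse-lattice candidate."""
        rng = np.random.default_rng(5)
        y = _grid_amps(sf0=0.06, tf0=3.0, xi=0.7) \
            + rng.normal(0.0, 0.05, (5, 6))
        fit = fit_spatiotemporal(y)

        def sse(sf0, tf0, xi, ssf=1.0, stf=1.0, A=None):
            model = spatiotemporal_response(
                np.asarray(SF_CENTERS_SFTF)[:, None],
                np.asarray(TF_CENTERS_SFTF)[None, :],
                1.0, sf0, tf0, ssf, stf, xi)
            A = (y * model).sum() / (model**2).sum()
            return ((A * model - y) ** 2).sum()

        fit_sse = ((fit.evaluate(np.asarray(SF_CENTERS_SFTF)[:, None],
                                 np.asarray(TF_CENTERS_SFTF)[None, :])
                    - y) ** 2).sum()
        best_grid = min(sse(sf0, tf0, xi)
                        for sf0 in np.logspace(np.log10(0.01),
                                               np.log10(0.64), 12)
                        for tf0 in np.logspace(np.log10(0.25),
                                               np.log10(32.0), 12)
                        for xi in np.linspace(-2.0, 2.0, 9))
        assert fit_sse <= best_grid + 1e-9

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            fit_spatiotemporal(np.zeros((5, 6)))

    def test_rejected_fits_still_report_parameters(self, rng):
        amps = rng.random((5, 6))  # structureless -> poor fit
        fit = fit_spatiotemporal(amps)
        assert np.isfinite(fit.sf0) and np.isfinite(fit.xi)


class TestSelectBestFit:
    def test_larger_amplitude_wins(self):
        best = select_best_fit(_fit(A=0.8), _fit(A=0.5, source="ANISO"))
        assert best.source == "ISO"

    def test_acceptance_gate_precedes_amplitude(self):
        best = select_best_fit(_fit(A=0.8, nrmse=0.5),
                               _fit(A=0.5, source="ANISO"))
        assert best.source == "ANISO"

    def test_tie_breaks_to_iso(self):
        best = select_best_fit(_fit(A=0.5), _fit(A=0.5, source="ANISO"))
        assert best.source == "ISO"

    def test_both_rejected_returns_none(self):
        assert select_best_fit(_fit(nrmse=0.2),
                               _fit(nrmse=0.3, source="ANISO")) is None


class TestFrequencyCutoffs:
    def test_closed_form_example(self):
        d = frequency_cutoffs(_fit())
        half = np.sqrt(2.0 * np.log(2.0))
        assert d.sf_low == pytest.approx(0.08 * 2.0**-half, rel=1e-6)
        assert d.sf_high == pytest.approx(0.08 * 2.0**half, rel=1e-6)
        assert d.sf_shape == "bandpass" and d.tf_shape == "bandpass"

    def test_low_cutoff_outside_range_is_lowpass(self):
        d = frequency_cutoffs(_fit(sf0=0.03, sigma_sf=2.0))
        assert d.sf_low < 0.02 < d.sf_high < 0.32
        assert d.sf_shape == "lowpass"

    def test_very_wide_tuning_is_broadband(self):
        d = frequency_cutoffs(_fit(sigma_sf=10.0))
        assert d.sf_shape == "broadband"

    def test_slant_shrinks_effective_sf_width(self):
        d0 = frequency_cutoffs(_fit(xi=0.0))
        d1 = frequency_cutoffs(_fit(xi=1.0))
        w0 = np.log2(d0.sf_high / d0.sf_low)
        w1 = np.log2(d1.sf_high / d1.sf_low)
        assert w1 == pytest.approx(w0 / np.sqrt(2.0), rel=1e-6)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(sf0=st.floats(0.02, 0.32), ssf=st.floats(0.4, 4.0),
           stf=st.floats(0.4, 4.0), xi=st.floats(-2.0, 2.0))
    def test_closed_form_agrees_with_numeric_root_finding(self, sf0, ssf,
                                                          stf, xi):
        fit = _fit(sf0=sf0, sigma_sf=ssf, sigma_tf=stf, xi=xi)
        d = frequency_cutoffs(fit)

        def slice_sf(lsf):
            return float(fit.evaluate(2.0**lsf, fit.tf0)) - fit.A / 2.0

        lo = brentq(slice_sf, np.log2(sf0) - 40 * ssf, np.log2(sf0))
        hi = brentq(slice_sf, np.log2(sf0), np.log2(sf0) + 40 * ssf)
        assert d.sf_low == pytest.approx(2.0**lo, rel=1e-6)
        assert d.sf_high == pytest.approx(2.0**hi, rel=1e-6)


class TestSpeed:
    def test_peak_speed_definition(self):
        assert peak_speed(_fit(sf0=0.08, tf0=2.0)) == pytest.approx(25.0)

    def test_boundary_xi_not_speed_tuned(self):
        assert not speed_flag(_fit(xi=0.5))
        assert speed_flag(_fit(xi=0.5 + 1e-9))


class TestAPI:
    @pytest.mark.parametrize("r1,r0,expected", [
        (0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.0, 1.0, -1.0),
        (0.4, 0.8, -1.0 / 3.0)])
    def test_values(self, r1, r0, expected):
        assert anisotropy_preference_index(r1, r0) \
            == pytest.approx(expected)

    @given(r1=st.floats(0.0, 10.0), r0=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, r1, r0):
        if r1 == 0 and r0 == 0:
            return
        assert anisotropy_preference_index(r1, r0) \
            == pytest.approx(-anisotropy_preference_index(r0, r1))

    def test_categories(self):
        assert api_category(-0.5) == "ISO-pref"
        assert api_category(0.5) == "ANISO-pref"
        assert api_category(0.0) == "mixed"
        assert api_category(-1.0 / 3.0 - 1e-9) == "ISO-pref"

    def test_double_zero_rejected(self):
        with pytest.raises(ValueError):
            anisotropy_preference_index(0.0, 0.0)


class TestElongationCurve:
    def test_curve_is_preferred_sf_row(self, rng):
        mat = rng.random((4, 4))
        mat[2] += 2.0
        curve, row = elongation_tuning_curve(mat)
        assert row == 2 and np.array_equal(curve, mat[2])

    def test_tie_breaks_to_lower_sf(self):
        mat = np.ones((4, 4))
        _, row = elongation_tuning_curve(mat)
        assert row == 0


class TestOrientationTimeCourse:
    fs = 20.0

    def test_delta_response_lands_in_matching_bin(self):
        trace = np.zeros(int(8 * self.fs))
        trace[int(1.0 * self.fs)] = 1.0  # theta(1 s) = 45 deg
        r_k, theta_k = orientation_time_course(trace, self.fs)
        assert np.flatnonzero(r_k).tolist() == [3]  # bin [45, 60)

    def test_post_offset_tail_wraps_to_onset_bins(self):
        """Calcium decay from a late-orientation response must be counted
        at the early orientations it spills into after wrap-around."""
        trace = np.zeros(int(8 * self.fs))
        t = np.arange(trace.size) / self.fs
        onset = 170.0 / 45.0  # response starts near the sweep's end
        mask = t >= onset
        trace[mask] = np.exp(-(t[mask] - onset) / 0.56)
        r_k, _ = orientation_time_course(trace, self.fs)
        assert r_k[0] > 0  # decay tail wrapped into the first bin

    def test_constant_trace_gives_flat_bins(self):
        r_k, _ = orientation_time_course(np.ones(int(8 * self.fs)), self.fs)
        assert np.allclose(r_k, r_k[0])

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            orientation_time_course(np.zeros(10), self.fs)


class TestOSI:
    theta_k = np.arange(12) * 15.0 + 7.5

    def test_flat_bins_give_zero(self):
        assert orientation_selectivity_index(np.ones(12), self.theta_k) \
            == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_gives_one(self):
        r = np.zeros(12)
        r[4] = 2.0
        assert orientation_selectivity_index(r, self.theta_k) \
            == pytest.approx(1.0)

    def test_orthogonal_bins_cancel(self):
        r_k = np.array([1.0, 1.0])
        assert orientation_selectivity_index(r_k, np.array([0.0, 90.0])) \
            == pytest.approx(0.0, abs=1e-12)

    def test_negative_bins_clipped(self):
        r_k = np.array([1.0, -5.0])
        assert orientation_selectivity_index(r_k, np.array([0.0, 90.0])) \
            == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            orientation_selectivity_index(np.zeros(12), self.theta_k)


class TestValidateOsi:
    @pytest.fixture(scope="class")
    def sweep(self):
        return validate_osi(fwhm_values=(10, 30, 60, 90, 120, 170),
                            seed=3)

    def test_spike_and_calcium_osi_strongly_correlated(self, sweep):
        rho = spearmanr(sweep["osi_spike"], sweep["osi_calc"]).statistic
        assert rho > 0.95

    def test_broad_tuning_yields_near_zero_osi(self, sweep):
        broad = sweep[sweep["fwhm"] == 170.0]
        assert broad["osi_spike"].mean() < 0.1
        assert broad["osi_calc"].mean() < 0.1

    def test_calcium_osi_invariant_to_preferred_orientation(self, sweep):
        per_pref = sweep[sweep["fwhm"] == 60.0]["osi_calc"]
        assert per_pref.max() - per_pref.min() < 0.1

    def test_spike_osi_decreases_with_bandwidth(self, sweep):
        means = sweep.groupby("fwhm")["osi_spike"].mean()
        assert np.all(np.diff(means.to_numpy()) < 0.02)  # Poisson slack
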