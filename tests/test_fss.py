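"""Contrast function, admissibility scale, and the annealed extraction."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fssfuse.fss import (AnnealSchedule, ContrastParams, EvokedAverage,
                         PhaseData, ZeroVarianceError, anneal_optimize,
                         contrast_F, estimate_k, evoked_average,
                         extract_source, g_logcosh, gauss_reference,
                         ica_decompose, negentropy_J, r_stim, saturation_H)
from fssfuse.preprocess import Recording, bandpass_narrow
from fssfuse.simulate import make_schedule, mix_to_sensors, simulate_sources

FS = 250.0


def make_phase(data, onsets, fs=FS, window=(-1.0, 7.0), phase_id="HAB"):
    rec = Recording(data=data, fs=fs,
                    channel_labels=[f"CH{i}" for i in range(data.shape[0])],
                    events=[])
    return PhaseData.from_recording(rec, np.asarray(onsets), window=window)


class TestNonlinearity:
    def test_zero_maps_to_zero(self):
        assert g_logcosh(0.0) == 0.0

    def test_closed_form_at_one(self):
        assert g_logcosh(1.0, 1.0) == pytest.approx(math.log(math.cosh(1.0)),
                                                    abs=1e-12)

    @given(st.floats(-50, 50), st.floats(1.0, 2.0))
    @settings(deadline=None, max_examples=50)
    def test_even_symmetry(self, u, a1):
        assert g_logcosh(-u, a1) == pytest.approx(g_logcosh(u, a1), rel=1e-12)

    def test_stable_for_huge_arguments(self):
        val = g_logcosh(1e6, 1.0)
        assert np.isfinite(val)
        assert val == pytest.approx(1e6 - math.log(2.0))


class TestGaussReference:
    def test_matches_independent_hermite_quadrature(self):
        """Gauss-Hermite oracle for E[log cosh v], v ~ N(0,1)."""
        nodes, weights = np.polynomial.hermite_e.hermegauss(80)
        oracle = float(np.sum(weights * np.log(np.cosh(nodes)))
                       / math.sqrt(2 * math.pi))
        assert gauss_reference(1.0) == pytest.approx(oracle, abs=1e-10)

    def test_depends_on_slope_constant(self):
        assert gauss_reference(2.0) != pytest.approx(gauss_reference(1.0), abs=1e-3)

    def test_constant_across_calls(self):
        assert gauss_reference(1.5) == gauss_reference(1.5)


class TestNegentropy:
    def test_near_zero_for_gaussian_sample(self):
        rng = np.random.default_rng(0)
        ph = make_phase(rng.standard_normal((1, 100_000)), onsets=[100.0])
        # bypass the narrowband assumption: J is defined on any projection
        ph.x = np.ascontiguousarray(rng.standard_normal((100_000, 1)),
                                    dtype=np.float32)
        assert negentropy_J(np.array([1.0]), ph, ContrastParams()) < 1e-4

    def test_two_point_distribution_closed_form(self):
        params = ContrastParams()
        rng = np.random.default_rng(1)
        u = rng.choice([-1.0, 1.0], size=200_000)
        ph = make_phase(u[None, :50_000], onsets=[60.0])
        ph.x = np.ascontiguousarray(u[:, None], dtype=np.float32)
        expected = (math.log(math.cosh(1.0)) - params.gauss_ref) ** 2
        assert expected == pytest.approx(3.5e-3, rel=0.02)
        assert negentropy_J(np.array([1.0]), ph, params) == pytest.approx(
            expected, rel=1e-4)

    def test_sign_flip_invariance_and_zero_variance_error(self):
        rng = np.random.default_rng(2)
        ph = make_phase(rng.standard_normal((2, 30_000)), onsets=[30.0, 60.0])
        w = np.array([0.3, -0.9])
        params = ContrastParams()
        assert negentropy_J(w, ph, params) == negentropy_J(-w, ph, params)
        ph.x = np.zeros_like(ph.x)
        with pytest.raises(ZeroVarianceError):
            negentropy_J(w, ph, params)


class TestStimulusResponse:
    def _ea(self, values):
        return EvokedAverage(values=values, fs=FS, window=(-1.0, 7.0))

    def test_gated_unit_sinusoid_reads_one(self):
        t = np.arange(-1.0, 7.0 + 1e-9, 1 / FS)
        v = np.where((t >= 0) & (t <= 5.0), np.sin(2 * np.pi * 10 * t), 0.0)
        r = r_stim(self._ea(v), ContrastParams())
        assert r == pytest.approx(1.0, abs=0.05)

    def test_zero_signal_gives_zero(self):
        t = np.arange(-1.0, 7.0 + 1e-9, 1 / FS)
        assert r_stim(self._ea(np.zeros_like(t)), ContrastParams()) == 0.0

    def test_equal_envelopes_cancel(self):
        t = np.arange(-1.0, 7.0 + 1e-9, 1 / FS)
        v = 0.7 * np.sin(2 * np.pi * 10 * t)
        assert r_stim(self._ea(v), ContrastParams()) == pytest.approx(0.0, abs=0.02)

    def test_window_must_cover_integral_limits(self):
        v = np.zeros(int(2 * FS) + 1)
        ea = EvokedAverage(values=v, fs=FS, window=(-1.0, 1.0))
        with pytest.raises(ValueError):
            r_stim(ea, ContrastParams())


class TestSaturation:
    @pytest.mark.parametrize("r,expected", [(1.0, 1.0), (0.5, 0.5), (2.0, 1.0),
                                            (0.0, 0.0), (-0.4, -0.4)])
    def test_branches(self, r, expected):
        assert saturation_H(r, 1.0) == expected

    @given(st.floats(-2, 4), st.floats(0.1, 3))
    @settings(deadline=None, max_examples=60)
    def test_bounded_and_monotone(self, r, k):
        h = saturation_H(r, k)
        assert h <= 1.0
        assert saturation_H(r + 0.5, k) >= h

    def test_requires_positive_scale(self):
        with pytest.raises(ValueError):
            saturation_H(0.5, 0.0)


class TestEvokedAverage:
    def test_single_epoch_is_that_epoch(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((1, int(20 * FS)))
        ph = make_phase(data, onsets=[5.0])
        w = np.array([1.0])
        ea = evoked_average(w, ph)
        sl = slice(int(4 * FS), int(12 * FS) + 1)
        sd = data[0].std()
        np.testing.assert_allclose(ea.values, data[0, sl] / sd, rtol=1e-5)

    def test_noise_average_shrinks_with_trial_count(self):
        rng = np.random.default_rng(4)
        amps = []
        for n_trials in (4, 64):
            data = rng.standard_normal((1, int((10 * n_trials + 20) * FS)))
            onsets = 5.0 + 10.0 * np.arange(n_trials)
            ph = make_phase(data, onsets)
            ea = evoked_average(np.array([1.0]), ph)
            amps.append(np.std(ea.values))
        assert amps[1] < amps[0] / 2  # expected 1/sqrt(16) = 1/4


def toy_two_channel(seed=0, n_trials=10, snr=4.0):
    """2-channel mixture: gated stimulus-locked 10 Hz + narrowband noise."""
    rng = np.random.default_rng(seed)
    iti = 4.0
    onsets = np.arange(n_trials) * (5.1 + iti) + 2.0
    dur = onsets[-1] + 5.1 + 8.0
    n = int(dur * FS)
    t = np.arange(n) / FS
    src = np.zeros(n)
    for o in onsets:
        g = (t >= o) & (t <= o + 5.1)
        src[g] = np.sin(2 * np.pi * 10 * (t[g] - o))
    from scipy import signal as sg
    sos = sg.butter(4, [9.0, 11.0], btype="bandpass", fs=FS, output="sos")
    noise = sg.sosfilt(sos, rng.standard_normal(n))
    noise /= noise.std() * snr
    a = np.array([[1.0, 0.6], [0.4, 1.0]])
    sensors = a @ np.vstack([src, noise])
    rec = Recording(data=sensors, fs=FS, channel_labels=["CH0", "CH1"], events=[])
    ph = PhaseData.from_recording(bandpass_narrow(rec), onsets)
    w_true = np.linalg.inv(a)[0]
    return ph, w_true / np.linalg.norm(w_true)


class TestAdmissibilityScale:
    def test_k_close_to_true_source_response(self):
        ph, w_true = toy_two_channel(seed=5)
        params = ContrastParams()
        k = estimate_k(ph, params, seed=1)
        r_true = r_stim(evoked_average(w_true, ph), params)
        assert abs(k - r_true) / r_true < 0.2

    def test_null_data_clamped_to_positive_floor(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((3, int(80 * FS)))
        rec = Recording(data=data, fs=FS, channel_labels=["a", "b", "c"], events=[])
        ph = PhaseData.from_recording(bandpass_narrow(rec),
                                      np.array([10.0, 30.0, 50.0]))
        k = estimate_k(ph, ContrastParams(), seed=2)
        assert k > 0
        assert k < 0.5  # no stimulus-locked structure

    def test_deterministic_given_seed(self):
        ph, _ = toy_two_channel(seed=7)
        k1 = estimate_k(ph, ContrastParams(), seed=3)
        ph.ica = None
        k2 = estimate_k(ph, ContrastParams(), seed=3)
        assert k1 == k2


class TestContrast:
    def test_lambda_zero_reduces_to_summed_negentropy(self):
        ph, _ = toy_two_channel(seed=8)
        w = np.array([0.8, 0.6])
        params0 = ContrastParams(lambda_weight=0.0)
        assert contrast_F(w, [ph], params0) == pytest.approx(
            negentropy_J(w, ph, params0), rel=1e-12)

    def test_sign_and_scale_invariance(self):
        ph, _ = toy_two_channel(seed=8)
        ph.k = 0.5
        w = np.array([0.8, 0.6])
        params = ContrastParams()
        f = contrast_F(w, [ph], params)
        assert contrast_F(-w, [ph], params) == pytest.approx(f, rel=1e-12)
        assert contrast_F(3.7 * w, [ph], params) == pytest.approx(f, rel=1e-6)

    def test_saturated_branch_adds_exactly_lambda(self):
        ph, w_true = toy_two_channel(seed=9)
        params = ContrastParams()
        ph.k = 1e-3  # far below the true response -> saturated
        f = contrast_F(w_true, [ph], params)
        j = negentropy_J(w_true, ph, params)
        assert f == pytest.approx(j + params.lambda_weight, rel=1e-9)


class TestAnneal:
    def test_recovers_true_unmixing_on_toy_mixture(self):
        ph, w_true = toy_two_channel(seed=10)
        params = ContrastParams()
        estimate_k(ph, params, seed=4)
        res = anneal_optimize([ph], params, AnnealSchedule(seed=5, subsample=1))
        assert abs(float(np.dot(res.w, w_true))) >= 0.99

    def test_trace_is_nondecreasing_and_deterministic(self):
        ph, _ = toy_two_channel(seed=11)
        params = ContrastParams()
        estimate_k(ph, params, seed=4)
        res1 = anneal_optimize([ph], params, AnnealSchedule(seed=6))
        res2 = anneal_optimize([ph], params, AnnealSchedule(seed=6))
        assert np.all(np.diff(res1.trace) >= 0)
        np.testing.assert_array_equal(res1.w, res2.w)
        np.testing.assert_array_equal(res1.trace, res2.trace)

    def test_lambda_zero_matches_best_fastica_component(self):
        """Annealed lambda=0 solution agrees with the max-J fastICA source."""
        ph, _ = toy_two_channel(seed=12)
        params0 = ContrastParams(lambda_weight=0.0)
        dec = ica_decompose(ph, params0, seed=7)
        ph.ica = dec
        res = anneal_optimize([ph], params0, AnnealSchedule(seed=8))
        best = dec.unmixing[int(np.argmax(dec.js))]
        s_ica = extract_source(best, ph)
        s_ann = extract_source(res.w, ph)
        assert abs(np.corrcoef(s_ica, s_ann)[0, 1]) >= 0.95

    def test_admissible_region_reached_at_optimum(self):
        ph, _ = toy_two_channel(seed=13)
        params = ContrastParams()
        estimate_k(ph, params, seed=9)
        res = anneal_optimize([ph], params, AnnealSchedule(seed=10))
        assert res.phase_diagnostics[ph.phase_id]["R_stim"] >= 0.8 * ph.k


class TestExtractSource:
    def test_unit_variance_and_sign_invariance(self):
        ph, w_true = toy_two_channel(seed=14)
        s = extract_source(w_true, ph)
        assert np.var(s) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(np.abs(extract_source(-w_true, ph)),
                                   np.abs(s), atol=1e-9)

    def test_identity_mixing_returns_standardized_source(self, small_sim_cfg):
        cfg = replace(small_sim_cfg, snr_sensor=np.inf, n_channels=12,
                      n_noise_sources=10)
        sch = make_schedule(cfg, "HAB")
        truth = simulate_sources(sch, cfg)
        truth.mixing_matrix = np.eye(12)
        rec = mix_to_sensors(truth, cfg, schedule=sch)
        ph = PhaseData.from_recording(rec, sch)  # no filtering: identity case
        w = np.zeros(12)
        w[truth.ssvep_index] = 1.0
        s = extract_source(w, ph)
        expected = truth.ssvep_source - truth.ssvep_source.mean()
        expected /= truth.ssvep_source.std()
        np.testing.assert_allclose(s, expected, atol=1e-4)
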