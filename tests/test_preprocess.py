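"""Filters, bad-channel detection, reference regression, HFC."""

import numpy as np
import pytest

from opmpipe import preprocess as pp
from opmpipe import simulate as sim
from opmpipe.forward import SensorArray


def _session_from(data, array, fs=1000.0, events=(1000, 2000)):
    return sim.RawSession(data, fs, np.array(events), array, "sub-01", 0)


@pytest.fixture()
def small_array():
    n = 6
    ori = np.zeros((n, 3))
    ori[:3] = np.eye(3)  # references, orthogonal
    ori[3:] = np.array([[0, 0, 1.0], [0, 1, 0.0], [1, 0, 0.0]])
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * 0.02
    pos[3:, 2] = 0.1
    names = ["R1", "R2", "R3", "S1", "S2", "S3"]
    ref = np.array([True] * 3 + [False] * 3)
    return SensorArray(names, pos, ori, ref)


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestFilters:
    def _mk(self, array, sig):
        data = np.tile(sig, (array.n_channels, 1))
        return _session_from(data, array)

    def test_notch_removes_line_frequency(self, array):
        t = np.arange(20_000) / 1000.0
        s = self._mk(array, np.sin(2 * np.pi * 60 * t))
        out = pp.notch_filter(s)
        assert _rms(out.data[0, 2000:-2000]) <= 0.01 * _rms(s.data[0])

    def test_notch_preserves_passband(self, array):
        t = np.arange(20_000) / 1000.0
        s = self._mk(array, np.sin(2 * np.pi * 25 * t))
        out = pp.notch_filter(s)
        assert _rms(out.data[0, 2000:-2000]) == pytest.approx(
            _rms(s.data[0, 2000:-2000]), rel=0.01)

    def test_notch_removes_all_harmonics(self, array):
        t = np.arange(20_000) / 1000.0
        sig = (np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 120 * t)
               + np.sin(2 * np.pi * 180 * t))
        out = pp.notch_filter(self._mk(array, sig))
        assert _rms(out.data[0, 2000:-2000]) <= 0.02 * _rms(sig)

    def test_notch_at_nyquist_rejected(self, array):
        s = self._mk(array, np.zeros(1000))
        with pytest.raises(ValueError):
            pp.notch_filter(s, freqs=(500.0,))

    def test_bandpass_attenuates_stopband(self, array):
        t = np.arange(30_000) / 1000.0
        s = self._mk(array, np.sin(2 * np.pi * 1.0 * t))
        out = pp.bandpass_filter(s)
        assert _rms(out.data[0, 5000:-5000]) <= 0.1 * _rms(s.data[0])

    def test_bandpass_preserves_passband(self, array):
        t = np.arange(30_000) / 1000.0
        s = self._mk(array, np.sin(2 * np.pi * 20 * t))
        out = pp.bandpass_filter(s)
        assert _rms(out.data[0, 5000:-5000]) == pytest.approx(
            _rms(s.data[0, 5000:-5000]), rel=0.05)

    def test_zero_phase_pulse_unshifted(self, array):
        n = 10_000
        k = 6000
        t = np.arange(n)
        pulse = np.exp(-0.5 * ((t - k) / 15.0) ** 2)
        s = self._mk(array, pulse)
        out = pp.bandpass_filter(pp.notch_filter(s))
        assert np.argmax(out.data[0]) == k

    def test_invalid_band_rejected(self, array):
        s = self._mk(array, np.zeros(1000))
        with pytest.raises(ValueError):
            pp.bandpass_filter(s, low=150.0, high=3.0)


class TestBadChannels:
    def test_planted_tone_channel_flagged(self, array, rng):
        n = 60_000
        t = np.arange(n) / 1000.0
        noise_rms = 1.0
        data = rng.standard_normal((array.n_channels, n)) * noise_rms
        bad_idx = 4  # scalp channel "C3"
        data[bad_idx] += 10 * noise_rms * np.sin(2 * np.pi * 130 * t)
        rep = pp.detect_bad_channels(_session_from(data, array))
        assert rep.flagged == [array.names[bad_idx]]

    def test_statistically_identical_channels_unflagged(self, array):
        sig = np.random.default_rng(0).standard_normal(30_000)
        data = np.tile(sig, (array.n_channels, 1))
        rep = pp.detect_bad_channels(_session_from(data, array))
        assert rep.flagged == []

    def test_infinite_threshold_flags_nothing(self, array, rng):
        data = rng.standard_normal((array.n_channels, 30_000))
        rep = pp.detect_bad_channels(_session_from(data, array),
                                     threshold=np.inf)
        assert rep.flagged == []

    def test_references_never_flagged(self, array, rng):
        data = rng.standard_normal((array.n_channels, 30_000))
        data[13] += 20 * np.sin(2 * np.pi * 130 * np.arange(30_000) / 1000)
        rep = pp.detect_bad_channels(_session_from(data, array))
        assert not set(rep.flagged) & {"REF_SUP", "REF_POST", "REF_LEFT"}

    def test_too_few_channels_rejected(self, small_array):
        keep = [0, 1, 2, 3, 4]  # only 2 scalp channels
        arr = SensorArray([small_array.names[i] for i in keep],
                          small_array.positions[keep],
                          small_array.orientations[keep],
                          small_array.is_reference[keep])
        with pytest.raises(ValueError):
            pp.detect_bad_channels(_session_from(np.zeros((5, 5000)), arr))


class TestReferenceRegression:
    def test_channel_equal_to_reference_zeroed(self, small_array, rng):
        data = rng.standard_normal((6, 5000))
        data[3] = data[0]
        out = pp.reference_regression(_session_from(data, small_array))
        assert _rms(out.data[3]) <= 1e-12 * _rms(data[3])

    def test_orthogonal_channel_unchanged(self, small_array, rng):
        t = np.arange(10_000) / 1000.0
        data = rng.standard_normal((6, 10_000)) * 0
        data[0] = np.sin(2 * np.pi * 5 * t)
        data[1] = np.sin(2 * np.pi * 7 * t)
        data[2] = np.sin(2 * np.pi * 9 * t)
        data[3] = np.sin(2 * np.pi * 11 * t) + 0.5
        out = pp.reference_regression(_session_from(data, small_array))
        expected = data[3] - data[3].mean()
        assert np.allclose(out.data[3], expected, atol=1e-8)

    def test_constructed_mixture_recovered(self, small_array):
        # integer-frequency sinusoids over full periods: s is exactly
        # orthogonal to every reference in-sample
        n = 20_000
        t = np.arange(n) / 1000.0
        r1, r2, r3 = (np.sin(2 * np.pi * f * t) for f in (5, 7, 9))
        s = np.sin(2 * np.pi * 13 * t)
        data = np.zeros((6, n))
        data[0], data[1], data[2] = r1, r2, r3
        data[3] = 0.5 * r1 - 2.0 * r2 + s
        out = pp.reference_regression(_session_from(data, small_array))
        target = s - s.mean()
        err = _rms(out.data[3] - target) / _rms(target)
        assert err <= 1e-6

    def test_residuals_orthogonal_to_references(self, small_array, rng):
        data = rng.standard_normal((6, 20_000))
        data[3:] += 0.7 * data[:3]
        out = pp.reference_regression(_session_from(data, small_array))
        for i in (3, 4, 5):
            for j in (0, 1, 2):
                r = np.corrcoef(out.data[i], data[j])[0, 1]
                assert abs(r) <= 1e-8

    def test_variance_never_increases(self, small_array, rng):
        data = rng.standard_normal((6, 5000))
        data -= data.mean(axis=1, keepdims=True)
        out = pp.reference_regression(_session_from(data, small_array))
        assert np.all(out.data[3:].var(axis=1) <= data[3:].var(axis=1) + 1e-15)

    def test_constant_reference_rejected(self, small_array, rng):
        data = rng.standard_normal((6, 5000))
        data[1] = 1.0
        with pytest.raises(ValueError):
            pp.reference_regression(_session_from(data, small_array))


class TestHfc:
    def test_homogeneous_interference_annihilated(self, array):
        spec = sim.NoiseSpec(gradient_fraction=0.0)
        _, project = sim.interference_timecourse(10_000, spec, 0)
        data = project(array.positions, array.orientations)
        res = pp.hfc(_session_from(data, array))
        scalp = ~array.is_reference
        assert (_rms(res.session.data[scalp])
                <= 1e-9 * _rms(data[scalp]))

    def test_idempotence(self, array, rng):
        data = rng.standard_normal((array.n_channels, 5000))
        once = pp.hfc(_session_from(data, array)).session
        twice = pp.hfc(once).session
        assert np.allclose(once.data, twice.data, atol=1e-16)

    def test_projector_symmetric_idempotent(self, array, rng):
        res = pp.hfc(_session_from(rng.standard_normal((16, 100)), array))
        P = res.projector
        assert np.max(np.abs(P - P.T)) <= 1e-12
        assert np.max(np.abs(P @ P - P)) <= 1e-9

    def test_attenuation_matches_brute_force(self, array, lead, rng):
        res = pp.hfc(_session_from(rng.standard_normal((16, 100)), array),
                     lead=lead)
        N = array.orientations[~array.is_reference]
        for j in range(0, lead.matrix.shape[1], 7):
            col = lead.matrix[:, j]
            coef, *_ = np.linalg.lstsq(N, col, rcond=None)
            resid = col - N @ coef
            expected = 1.0 - np.linalg.norm(resid) / np.linalg.norm(col)
            assert res.attenuation[j] == pytest.approx(expected, abs=1e-12)

    def test_signals_orthogonal_to_model_pass(self, array, rng):
        scalp = ~array.is_reference
        N = array.orientations[scalp]
        P = pp.hfc_projector(N)[0]
        x = rng.standard_normal((scalp.sum(), 2000))
        x_perp = P @ x  # already orthogonal to span(N)
        data = np.zeros((array.n_channels, 2000))
        data[scalp] = x_perp
        out = pp.hfc(_session_from(data, array)).session
        assert np.allclose(out.data[scalp], x_perp, atol=1e-9)

    def test_rank_deficient_orientation_warns(self):
        ori = np.tile(np.array([[0.0, 0.0, 1.0]]), (5, 1))
        with pytest.warns(RuntimeWarning, match="rank"):
            P, rank = pp.hfc_projector(ori)
        assert rank == 1

    def test_partial_array_attenuates_more_than_whole_cap(self, head, grid,
                                                          lead):
        from opmpipe.forward import SensorArray, compute_lead_field

        # synthetic 64-sensor whole-cap comparison array (radial, Fibonacci
        # spiral over the upper hemisphere)
        n = 64
        k = np.arange(n) + 0.5
        z = 1 - k / n  # upper hemisphere
        phi = np.pi * (1 + np.sqrt(5)) * k
        dirs = np.column_stack([np.sqrt(1 - z**2) * np.cos(phi),
                                np.sqrt(1 - z**2) * np.sin(phi), z])
        arr64 = SensorArray([f"S{i}" for i in range(n)],
                            head.center + 0.10 * dirs, dirs,
                            np.zeros(n, bool))
        lead64 = compute_lead_field(arr64, grid, head)
        P64 = pp.hfc_projector(arr64.orientations)[0]
        att64 = 1 - (np.linalg.norm(P64 @ lead64.matrix, axis=0)
                     / np.linalg.norm(lead64.matrix, axis=0))
        from opmpipe.forward import build_default_array
        arr13 = build_default_array(head).scalp()
        P13 = pp.hfc_projector(arr13.orientations)[0]
        att13 = 1 - (np.linalg.norm(P13 @ lead.matrix, axis=0)
                     / np.linalg.norm(lead.matrix, axis=0))
        assert att13.mean() > att64.mean()


class TestPreprocessAll:
    def test_interference_only_session_suppressed(self, array):
        spec = sim.NoiseSpec(gradient_fraction=0.0)
        _, project = sim.interference_timecourse(60_000, spec, 3)
        data = project(array.positions, array.orientations)
        s = _session_from(data, array, events=(5000, 15000))
        out, _ = pp.preprocess_all(s, drop_bad=False)
        scalp = ~array.is_reference
        assert out.data.var() <= 0.01 * data[scalp].var()

    def test_hfc_off_leaves_more_variance(self, array, head, grid, lead):
        s = sim.generate_session(sim.SHORT_MNS, sim.SourceScenario(),
                                 sim.NoiseSpec(), array, head, "sub-01", 9,
                                 grid=grid, lead=lead)
        with_hfc, _ = pp.preprocess_all(s, apply_hfc=True, drop_bad=False)
        without, _ = pp.preprocess_all(s, apply_hfc=False, drop_bad=False)
        assert without.data.var() > with_hfc.data.var()

    def test_noiseless_sef_latency_preserved(self, array, head, grid, lead):
        # a vanishing noise floor (1e-18 T/√Hz) keeps the reference
        # channels non-constant without perturbing the SEF
        silent = sim.NoiseSpec(sensor_noise_density=1e-18,
                               interference_rms=0.0,
                               line_amplitudes=(0.0, 0.0, 0.0),
                               artifact_amplitude=0.0)
        scen = sim.SourceScenario(
            latency_jitter_sd=0.0, amplitude_jitter_sd=0.0,
            mu_source=sim.OscillatorySource(52, 10.0, 0.0),
            beta_erd_source=sim.OscillatorySource(52, 21.0, 0.0),
            beta_ers_source=sim.OscillatorySource(32, 21.0, 0.0),
        )
        s = sim.generate_session(sim.SHORT_MNS, scen, silent, array, head,
                                 "sub-01", 5, grid=grid, lead=lead)
        out, _ = pp.preprocess_all(s, drop_bad=False)
        ch = np.argmax(np.abs(s.data[:13]).max(axis=1))
        ev = s.events[10]
        sl = slice(ev + 10, ev + 31)  # 10–30 ms post-stimulus
        before = np.argmin(s.data[ch, sl])
        after = np.argmin(out.data[ch, sl])
        assert before == after
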