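"""Butterworth design, filtering, and the LMS mains canceller."""

import numpy as np
import pytest
from scipy import signal as sps

from ecgbeats.preprocess import (
    ButterworthSpec,
    LmsState,
    PreprocessConfig,
    apply_filter,
    butterworth_order,
    butterworth_poles,
    design_lowpass,
    lms_cancel,
    preprocess_record,
)
from ecgbeats.synth import DatasetSpec, NoiseSpec, generate_dataset

FS = 360.0


def bin_magnitude(sig: np.ndarray, freq: float, fs: float) -> float:
    """Single-bin discrete Fourier magnitude at ``freq``."""
    n = len(sig)
    k = np.exp(-2j * np.pi * freq * np.arange(n) / fs)
    return 2.0 * abs(np.dot(sig, k)) / n


class TestDesign:
    def test_order_formula_against_scipy_buttord(self):
        for spec in (ButterworthSpec(),
                     ButterworthSpec(passband_hz=40, stopband_hz=60,
                                     ap_db=1.0, as_db=30.0),
                     ButterworthSpec(passband_hz=80, stopband_hz=100,
                                     ap_db=3.0, as_db=40.0)):
            n_ref, _ = sps.buttord(spec.omega_p, spec.omega_s,
                                   spec.ap_db, spec.as_db, analog=True)
            assert butterworth_order(spec) == n_ref

    def test_n2_prototype_poles(self):
        # enumerate candidates on the unit circle, keep the stable pair
        poles = butterworth_poles(2, 1.0)
        want = {np.exp(3j * np.pi / 4), np.exp(5j * np.pi / 4)}
        got = set(np.round(poles, 12))
        assert {complex(np.round(w, 12)) for w in want} == got

    @pytest.mark.parametrize("order", [1, 2, 3, 5])
    def test_all_retained_poles_stable(self, order):
        poles = butterworth_poles(order, 2 * np.pi * 100)
        assert len(poles) == order
        assert np.all(poles.real < 0)

    def test_analog_magnitude_law(self):
        coeffs = design_lowpass(ButterworthSpec())
        assert coeffs.analog_magnitude(0.0) == pytest.approx(1.0)
        assert coeffs.analog_magnitude(coeffs.omega_c) == \
            pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_discrete_filter_unity_dc_gain_and_stability(self):
        for spec in (ButterworthSpec(),
                     ButterworthSpec(passband_hz=40, stopband_hz=60,
                                     ap_db=1.0, as_db=30.0)):
            coeffs = design_lowpass(spec)
            assert coeffs.magnitude(0.0) == pytest.approx(1.0, abs=1e-6)
            assert np.all(np.abs(np.roots(coeffs.a)) < 1.0)
            assert coeffs.a[0] == 1.0

    def test_prewarped_design_hits_minus_3db_at_cutoff(self):
        spec = ButterworthSpec(passband_hz=40, stopband_hz=60,
                               ap_db=1.0, as_db=30.0, prewarp=True)
        coeffs = design_lowpass(spec)
        fc = coeffs.omega_c / (2 * np.pi)
        # the prewarped analog cutoff maps back through tan; recover the
        # digital -3 dB frequency and check the response there
        f_digital = FS / np.pi * np.arctan(coeffs.omega_c / (2 * FS))
        assert coeffs.magnitude(f_digital) == pytest.approx(1 / np.sqrt(2),
                                                            rel=1e-6)
        del fc

    def test_matches_scipy_butter_reference(self):
        """Same order + prewarped cutoff must match scipy's digital design."""
        spec = ButterworthSpec(passband_hz=40, stopband_hz=60,
                               ap_db=1.0, as_db=30.0, prewarp=True)
        coeffs = design_lowpass(spec)
        f3db = FS / np.pi * np.arctan(coeffs.omega_c / (2 * FS))
        b_ref, a_ref = sps.butter(coeffs.order, f3db, fs=FS)
        freqs = np.linspace(1, 170, 40)
        _, h_ref = sps.freqz(b_ref, a_ref, worN=2 * np.pi * freqs / FS)
        assert np.allclose(coeffs.magnitude(freqs), np.abs(h_ref), rtol=1e-6)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            ButterworthSpec(passband_hz=100, stopband_hz=80)
        with pytest.raises(ValueError):
            ButterworthSpec(passband_hz=80, stopband_hz=80)


class TestApplyFilter:
    def test_zero_and_constant_signals(self):
        coeffs = design_lowpass(ButterworthSpec())
        assert np.allclose(apply_filter(coeffs, np.zeros(100)), 0.0)
        out = apply_filter(coeffs, np.full(2000, 2.5))
        assert out[-1] == pytest.approx(2.5, rel=1e-6)  # unity DC, steady state

    def test_frequency_response_oracle_on_long_sinusoids(self):
        coeffs = design_lowpass(ButterworthSpec(passband_hz=40, stopband_hz=60,
                                                ap_db=1.0, as_db=30.0))
        t = np.arange(int(20 * FS)) / FS
        for f in (10.0, 150.0):
            out = apply_filter(coeffs, np.sin(2 * np.pi * f * t))
            tail = out[len(out) // 2:]
            amp = bin_magnitude(tail, f, FS)
            assert amp == pytest.approx(coeffs.magnitude(f), rel=0.01)
        # low-pass: more attenuation at 150 Hz than at 10 Hz
        assert coeffs.magnitude(150.0) < coeffs.magnitude(10.0)

    def test_empty_signal_rejected(self):
        coeffs = design_lowpass(ButterworthSpec())
        with pytest.raises(ValueError):
            apply_filter(coeffs, np.array([]))


class TestLms:
    def test_mu_zero_is_identity(self):
        t = np.arange(1000) / FS
        d = np.sin(2 * np.pi * 50 * t) + 0.1 * np.sin(2 * np.pi * 7 * t)
        out, state = lms_cancel(d, LmsState(mu=0.0))
        assert np.array_equal(out, d)
        assert state.w1 == 0.0 and state.w2 == 0.0

    def test_matched_50hz_cancelled_below_one_percent(self):
        t = np.arange(int(10 * FS)) / FS
        d = np.sin(2 * np.pi * 50 * t + 1.1)
        out, _ = lms_cancel(d, LmsState(mu=0.1))
        tail = len(d) // 10
        assert np.mean(out[-tail:] ** 2) < 0.01 * np.mean(d ** 2)

    def test_orthogonal_10hz_passes_through(self):
        # misadjustment scales with mu; at mu=0.02 the passthrough is clean
        t = np.arange(int(30 * FS)) / FS
        d = np.sin(2 * np.pi * 10 * t)
        out, _ = lms_cancel(d, LmsState(mu=0.02))
        tail = len(d) // 10
        assert np.mean(out[-tail:] ** 2) == pytest.approx(
            np.mean(d[-tail:] ** 2), rel=0.05)

    def test_references_in_quadrature(self):
        state = LmsState()
        quarter = FS / (4 * state.ref_freq)
        n = np.arange(100)
        x1, x2 = state.references(n)
        x1_shifted, _ = state.references(n - quarter)
        assert np.allclose(x2, x1_shifted, atol=1e-12)

    def test_weight_convergence_on_stationary_interference(self):
        t = np.arange(int(10 * FS)) / FS
        d = 0.7 * np.sin(2 * np.pi * 50 * t + 0.3)
        state = LmsState(mu=0.1)
        # run all but the last 100 samples, then watch the weight trajectory
        _, state = lms_cancel(d[:-100], state)
        w_hist = []
        for sample in d[-100:]:
            _, state = lms_cancel(np.array([sample]), state)
            w_hist.append((state.w1, state.w2))
        w = np.array(w_hist)
        span = np.abs(np.diff(w, axis=0)).max()
        assert span < 1e-3 * np.abs(w).max()

    def test_divergence_raises_with_iteration_number(self):
        t = np.arange(2000) / FS
        d = 100.0 * np.sin(2 * np.pi * 50 * t)
        with pytest.raises(FloatingPointError, match="iteration"):
            lms_cancel(d, LmsState(mu=50.0))

    def test_state_continuity_across_chunks(self):
        t = np.arange(int(4 * FS)) / FS
        d = np.sin(2 * np.pi * 50 * t + 0.5)
        whole, _ = lms_cancel(d, LmsState())
        state = LmsState()
        parts = []
        for chunk in np.array_split(d, 7):
            out, state = lms_cancel(chunk, state)
            parts.append(out)
        assert np.allclose(np.concatenate(parts), whole, atol=1e-12)


class TestPreprocessRecord:
    def _noisy_record(self, seed=21):
        records, _ = generate_dataset(
            DatasetSpec(counts={c: 20 for c in "ALNRV"}, seed=seed),
            NoiseSpec(powerline_amplitude=0.5, powerline_phase=0.8,
                      emg_rms=0.05, baseline_amplitude=0.05))
        return records[0]

    def test_disabled_stages_are_identity(self):
        rec = self._noisy_record()
        out = preprocess_record(rec, PreprocessConfig(lowpass=False, lms=False))
        assert np.array_equal(out.samples, rec.samples)

    def test_50hz_suppressed_at_least_20db(self):
        rec = self._noisy_record()
        out = preprocess_record(rec)
        skip = int(rec.fs)  # ignore the adaptation transient
        before = bin_magnitude(rec.samples[skip:], 50.0, rec.fs)
        after = bin_magnitude(out.samples[skip:], 50.0, rec.fs)
        assert 20 * np.log10(before / after) >= 20.0

    def test_length_and_annotations_preserved(self):
        rec = self._noisy_record()
        out = preprocess_record(rec)
        assert len(out.samples) == len(rec.samples)
        assert [(a.index, a.symbol) for a in out.annotations] == \
               [(a.index, a.symbol) for a in rec.annotations]

    def test_energy_not_amplified_on_bandlimited_noise(self, rng):
        coeffs = design_lowpass(ButterworthSpec())
        noise = rng.standard_normal(10_000)
        out = apply_filter(coeffs, noise)
        assert np.mean(out ** 2) <= np.mean(noise ** 2) * 1.05
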