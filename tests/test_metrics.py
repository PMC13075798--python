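import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lanmm.metrics import (
    LyapunovPair,
    Spectrum,
    bandpass_phase_amp,
    benettin_les,
    classify_regime,
    dominant_frequency,
    frequency_map,
    pac_from_timeseries,
    psd,
    regime_map,
    tort_mi,
)
from lanmm.params import ModelParams
from lanmm.simulate import SolverSettings, TimeSeries, integrate


def _tone(freq, fs=1000.0, seconds=30.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return TimeSeries(t=t, vP1=amp * np.sin(2 * np.pi * freq * t),
                      vP2=amp * np.sin(2 * np.pi * freq * t), sample_rate=fs)


class TestPsd:
    def test_pure_tone_peak(self):
        s = psd(_tone(10.0), "vP1")
        assert dominant_frequency(s) == pytest.approx(10.0, abs=0.1)

    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60000)
        t = np.arange(60000) / 1000.0
        ts = TimeSeries(t=t, vP1=x, vP2=x, sample_rate=1000.0)
        s = psd(ts, "vP1")
        df = s.freqs[1] - s.freqs[0]
        assert np.sum(s.power) * df == pytest.approx(np.var(x), rel=0.05)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            psd(_tone(10.0, seconds=5.0), "vP1")

    def test_multifrequency_point_has_both_peaks(self, table1, spectral_settings):
        # at the baseline operating point the superficial pyramidal signal
        # carries both the shared alpha rhythm and its own gamma rhythm
        ts = integrate(table1.with_inputs(200.0, 90.0), spectral_settings)
        s = psd(ts, "vP2")

        def band_peak(lo, hi):
            m = (s.freqs >= lo) & (s.freqs <= hi)
            return s.freqs[m][np.argmax(s.power[m])]

        assert band_peak(8, 13) == pytest.approx(10.0, abs=1.0)
        assert band_peak(30, 50) == pytest.approx(40.0, abs=3.0)


class TestDominantFrequency:
    def test_exclusion_band(self):
        f = np.linspace(0.5, 100, 1000)
        p = np.full_like(f, 1e-3)
        p[np.argmin(np.abs(f - 20.0))] = 5.0
        p[np.argmin(np.abs(f - 40.0))] = 1.0
        s = Spectrum(freqs=f, power=p)
        assert dominant_frequency(s) == pytest.approx(20.0, abs=0.2)
        assert dominant_frequency(s, exclude_band=(12, 30)) == pytest.approx(40.0, abs=0.2)

    def test_tie_breaks_toward_lower_frequency(self):
        f = np.linspace(1, 50, 100)
        p = np.zeros_like(f)
        p[10] = p[60] = 1.0
        assert dominant_frequency(Spectrum(freqs=f, power=p)) == pytest.approx(f[10])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(Spectrum(freqs=np.array([1.0, 2.0]), power=np.zeros(2)))

    def test_floor_returns_none_when_only_subthreshold_power_remains(self):
        # all real power sits below the 0.5 Hz cutoff (slow drift); what is
        # left above it is numerically negligible, so no rhythm is reported
        f = np.linspace(0.1, 100, 1000)
        p = np.where(f < 0.5, 1.0, 1e-14)
        assert dominant_frequency(Spectrum(freqs=f, power=p)) is None


class TestBandpass:
    def test_phase_advances_at_tone_frequency(self):
        ts = _tone(10.0)
        ph = bandpass_phase_amp(ts, (8, 13), "phase")
        slope = np.polyfit(ts.t[2000:-2000], np.unwrap(ph)[2000:-2000], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_envelope_flat_for_constant_tone(self):
        ts = _tone(10.0, amp=2.0)
        env = bandpass_phase_amp(ts, (8, 13), "amplitude")
        core = env[3000:-3000]
        assert np.ptp(core) / np.mean(core) < 0.02
        assert np.mean(core) == pytest.approx(2.0, rel=0.02)

    def test_zero_phase_preserves_pulse_center(self):
        fs = 1000.0
        n = 4096
        x = np.zeros(n)
        x[n // 2 - 50 : n // 2 + 51] = np.hanning(101)
        t = np.arange(n) / fs
        ts = TimeSeries(t=t, vP1=x, vP2=x, sample_rate=fs)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [2.0, 30.0], btype="bandpass", fs=fs, output="sos")
        y = sosfiltfilt(sos, x)
        com_in = np.sum(t * x) / np.sum(x)
        com_out = np.sum(t * np.abs(y)) / np.sum(np.abs(y))
        assert abs(com_in - com_out) <= 1.0 / fs

    def test_invalid_band_rejected(self):
        ts = _tone(10.0)
        with pytest.raises(ValueError):
            bandpass_phase_amp(ts, (30, 10), "phase")
        with pytest.raises(ValueError):
            bandpass_phase_amp(ts, (10, 2000), "phase")


class TestTortMi:
    def test_uniform_amplitude_gives_zero(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, 100000)
        amp = rng.uniform(0.5, 1.5, 100000)
        assert tort_mi(phase, amp).mi < 0.01

    def test_concentrated_amplitude_approaches_one(self):
        phase = np.linspace(-np.pi, np.pi, 36000, endpoint=False)
        # all amplitude inside exactly one 20-degree bin ([0, pi/9))
        amp = np.where((phase >= 0) & (phase < np.pi / 9), 1.0, 1e-12)
        assert tort_mi(phase, amp).mi > 0.95

    def test_rescaling_invariance(self):
        # MI depends only on the normalized phase-binned distribution, so a
        # positive rescale of the amplitude leaves it unchanged
        rng = np.random.default_rng(2)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.uniform(0, 1, 5000)
        assert tort_mi(phase, amp).mi == pytest.approx(tort_mi(phase, 7.3 * amp).mi,
                                                       rel=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mi_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, 2000)
        amp = rng.gamma(1.0, 1.0, 2000)
        assert 0.0 <= tort_mi(phase, amp).mi <= 1.0

    def test_empty_bins_rejected(self):
        phase = np.zeros(100)  # all in one bin
        with pytest.raises(ValueError):
            tort_mi(phase, np.ones(100))

    def test_monotone_in_synthetic_coupling_depth(self):
        from lanmm.synth import SyntheticPACSpec, synthetic_pac_signal

        mis = []
        for d in (0.0, 0.25, 0.5, 0.75, 1.0):
            ts = synthetic_pac_signal(SyntheticPACSpec(coupling_depth=d))
            mis.append(pac_from_timeseries(ts, (3, 7), (30, 50),
                                           phase_channel="vP1", amp_channel="vP1").mi)
        assert all(a <= b for a, b in zip(mis, mis[1:]))
        assert mis[0] < 0.01


class TestBenettin:
    def test_steady_regime_matches_linear_theory(self, table1):
        # at a stable equilibrium the leading exponent is the slowest
        # eigenvalue's real part
        from lanmm.equilibria import find_equilibrium

        pm = table1.with_inputs(50.0, 0.0)
        le = benettin_les(pm, t_accumulate=100.0)
        eq = find_equilibrium(pm)
        assert eq.stable
        assert le.lambda1 == pytest.approx(eq.eigenvalues.real.max(), rel=0.05)
        assert le.lambda1 < 0

    def test_periodic_regime_zero_and_negative(self, table1):
        le = benettin_les(table1.with_inputs(250.0, 0.0))
        assert abs(le.lambda1) <= 0.05
        assert le.lambda2 < -0.05

    def test_quasiperiodic_at_baseline_point(self, table1):
        # (200, 90) sits just past the torus bifurcation: two zero exponents
        le = benettin_les(table1.with_inputs(200.0, 90.0))
        assert abs(le.lambda1) <= 0.05
        assert abs(le.lambda2) <= 0.05

    def test_reference_systems_within_five_percent(self):
        from lanmm.synth import benettin_reference, reference_le_system

        sys_lin = reference_le_system("linear_stable")
        l1, l2 = benettin_reference(sys_lin, t_accumulate=50.0)
        assert l1 == pytest.approx(-1.0, abs=0.05)
        assert l2 == pytest.approx(-3.0, abs=0.15)

        sys_cycle = reference_le_system("harmonic_pair")
        l1, l2 = benettin_reference(sys_cycle, t_accumulate=100.0)
        assert l1 == pytest.approx(0.0, abs=0.05)
        assert l2 == pytest.approx(-2.0, rel=0.05)

        sys_torus = reference_le_system("quasiperiodic_torus_flow")
        l1, l2 = benettin_reference(sys_torus, t_accumulate=50.0)
        assert abs(l1) <= 0.05 and abs(l2) <= 0.05


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "l1,l2,expected",
        [
            (-2.0, -5.0, "steady"),
            (0.001, -1.2, "periodic"),
            (0.002, -0.003, "quasiperiodic"),
            (0.8, 0.001, "chaotic"),
        ],
    )
    def test_labels(self, l1, l2, expected):
        assert classify_regime(LyapunovPair(l1, l2, 0.0), tol=0.05) == expected


class TestMaps:
    def test_single_cell_frequency_map(self, table1):
        fm = frequency_map(table1, [250.0], [0.0],
                           SolverSettings(t_transient=10.0, t_record=20.0))
        assert fm.freq_vP1.shape == (1, 1)
        assert fm.freq_vP1[0, 0] == pytest.approx(10.0, abs=1.0)

    def test_multifrequency_cell_flagged(self, table1):
        fm = frequency_map(table1, [125.0], [307.0],
                           SolverSettings(t_transient=10.0, t_record=30.0))
        assert bool(fm.multifrequency[0, 0])
        assert fm.freq_vP1[0, 0] < 12.0
        assert fm.freq_vP2[0, 0] > 30.0

    def test_steady_cell_has_no_frequency(self, table1):
        fm = frequency_map(table1, [50.0], [0.0],
                           SolverSettings(t_transient=10.0, t_record=30.0))
        assert np.isnan(fm.freq_vP1[0, 0])
        assert not bool(fm.multifrequency[0, 0])

    def test_single_cell_regime_map(self, table1):
        rm = regime_map(table1, [50.0], [0.0], t_accumulate=50.0)
        assert rm.labels[0, 0] == "steady"
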