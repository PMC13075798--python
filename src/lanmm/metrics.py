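"""Spectral analysis, phase-amplitude coupling, and Lyapunov-based regime maps.

Spectra are Welch estimates on DC-removed observables (10 s Hann segments at
50% overlap by default, giving 0.1 Hz resolution).  The dominant frequency is
the raw PSD argmax outside an optional exclusion band (the model produces no
significant 12-30 Hz power, so that band is excluded when comparing slow and
fast rhythms); no aperiodic-background correction is applied.

Phase-amplitude coupling uses the Tort modulation index: phases binned into
18 bins of 20 degrees, mean fast-band envelope per bin normalized into a
distribution P, MI = KL(P || uniform) / log(n_bins) in [0, 1].  Band
extraction is a zero-phase (forward-backward) 4th-order Butterworth filter
followed by the analytic-signal phase or envelope.

The two largest Lyapunov exponents come from the Benettin method: the flow
plus two tangent vectors integrated together, Gram-Schmidt re-orthonormalized
at fixed intervals, exponents from the accumulated log stretch factors.
Regimes are classified by (lambda1, lambda2): steady (-,-), periodic (0,-),
quasiperiodic (0,0), chaotic (+,.).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt, welch

from . import _fast
from .params import ModelParams
from .simulate import SolverSettings, TimeSeries, integrate

__all__ = [
    "Spectrum",
    "PACResult",
    "LyapunovPair",
    "RegimeMap",
    "FrequencyMap",
    "psd",
    "dominant_frequency",
    "frequency_map",
    "bandpass_phase_amp",
    "tort_mi",
    "pac_from_timeseries",
    "benettin_les",
    "classify_regime",
    "regime_map",
]

#: spectral floor: a peak below this fraction of total power means "no
#: oscillation" (prevents noise-floor argmax artifacts on steady cells)
POWER_FLOOR = 1e-6

#: |lambda| below this (1/s) counts as a zero exponent in regime labels
LE_ZERO_TOL = 0.05


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density (mV^2/Hz) on an increasing grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.power):
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


@dataclass(frozen=True)
class PACResult:
    """Tort modulation index between a phase band and an amplitude band."""

    phase_band: tuple
    amp_band: tuple
    n_bins: int
    mi: float
    bin_mean_amplitudes: np.ndarray


@dataclass(frozen=True)
class LyapunovPair:
    """Two largest Lyapunov exponents (1/s), sorted lambda1 >= lambda2."""

    lambda1: float
    lambda2: float
    convergence_error: float


@dataclass
class RegimeMap:
    """Regime label per cell of a rectangular (phi_e1, phi_e2) grid."""

    phi1: np.ndarray
    phi2: np.ndarray
    labels: np.ndarray  # (len(phi2), len(phi1)) of str
    lambda1: np.ndarray
    lambda2: np.ndarray


@dataclass
class FrequencyMap:
    """Dominant frequency per observable per cell; multifrequency flags."""

    phi1: np.ndarray
    phi2: np.ndarray
    freq_vP1: np.ndarray
    freq_vP2: np.ndarray
    multifrequency: np.ndarray


# --------------------------------------------------------------------------- #
# spectra
# --------------------------------------------------------------------------- #


def psd(ts: TimeSeries, channel: str = "vP1", segment_seconds: float = 10.0) -> Spectrum:
    """Welch PSD of one observable channel, DC removed.

    Requires at least two segments of data; frequency resolution is
    1/segment_seconds (0.1 Hz at the default).
    """
    x = ts.channel(channel)
    nper = int(round(segment_seconds * ts.sample_rate))
    if len(x) < 2 * nper:
        raise ValueError(
            f"need >= {2 * nper} samples ({2 * segment_seconds:.0f} s) for the Welch "
            f"estimate, got {len(x)}"
        )
    f, p = welch(x - x.mean(), fs=ts.sample_rate, window="hann",
                 nperseg=nper, noverlap=nper // 2)
    return Spectrum(freqs=f[1:], power=p[1:])  # drop the DC bin


def dominant_frequency(
    s: Spectrum,
    exclude_band: tuple | None = None,
    f_min: float = 0.5,
) -> float | None:
    """Frequency of maximum power outside the excluded band and above f_min.

    Returns None when the spectrum has no peak above the relative power floor
    (a steady state).  Ties break toward the lower frequency (argmax picks
    the first maximum).
    """
    if len(s.freqs) == 0 or not np.any(s.power > 0):
        raise ValueError("empty or all-zero spectrum")
    total = float(np.sum(s.power))
    mask = s.freqs >= f_min
    if exclude_band is not None:
        lo, hi = exclude_band
        mask &= ~((s.freqs >= lo) & (s.freqs <= hi))
    if not np.any(mask):
        return None
    p = np.where(mask, s.power, 0.0)
    i = int(np.argmax(p))
    if p[i] < POWER_FLOOR * total:
        return None
    return float(s.freqs[i])


def frequency_map(
    params: ModelParams,
    phi1_grid,
    phi2_grid,
    settings: SolverSettings | None = None,
    exclude_band: tuple = (12.0, 30.0),
    gamma_threshold: float = 30.0,
) -> FrequencyMap:
    """Dominant frequency of vP1 and vP2 over a (phi_e1, phi_e2) grid.

    Cells where the two observables fall in different bands (one below the
    excluded band, the other in the gamma range) are flagged multifrequency;
    steady cells carry NaN.  Failed integrations are marked invalid (NaN)
    rather than dropped.
    """
    settings = settings or SolverSettings(t_transient=10.0, t_record=30.0)
    p1 = np.asarray(phi1_grid, dtype=float)
    p2 = np.asarray(phi2_grid, dtype=float)
    f1 = np.full((len(p2), len(p1)), np.nan)
    f2 = np.full((len(p2), len(p1)), np.nan)
    multi = np.zeros((len(p2), len(p1)), dtype=bool)
    for j, b in enumerate(p2):
        for i, a in enumerate(p1):
            pr = params.with_inputs(float(a), float(b))
            try:
                ts = integrate(pr, settings)
                sp1 = psd(ts, "vP1", segment_seconds=min(10.0, settings.t_record / 2))
                sp2 = psd(ts, "vP2", segment_seconds=min(10.0, settings.t_record / 2))
            except Exception:
                continue

            def _dom(sp):
                try:
                    return dominant_frequency(sp, exclude_band)
                except ValueError:  # all-zero spectrum: exactly steady cell
                    return None

            d1, d2 = _dom(sp1), _dom(sp2)
            f1[j, i] = np.nan if d1 is None else d1
            f2[j, i] = np.nan if d2 is None else d2
            if d1 is not None and d2 is not None:
                multi[j, i] = (d1 < exclude_band[0]) and (d2 >= gamma_threshold)
    return FrequencyMap(phi1=p1, phi2=p2, freq_vP1=f1, freq_vP2=f2, multifrequency=multi)


# --------------------------------------------------------------------------- #
# phase-amplitude coupling
# --------------------------------------------------------------------------- #


def bandpass_phase_amp(
    ts: TimeSeries,
    band: tuple,
    extract: str,
    channel: str = "vP1",
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, then Hilbert phase or envelope.

    ``extract`` is "phase" (radians, wrapped) or "amplitude" (envelope, mV).
    """
    lo, hi = band
    nyq = ts.sample_rate / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) or not increasing")
    if extract not in ("phase", "amplitude"):
        raise ValueError(f"extract must be 'phase' or 'amplitude', got {extract!r}")
    x = ts.channel(channel)
    sos = butter(order, [lo, hi], btype="bandpass", fs=ts.sample_rate, output="sos")
    y = sosfiltfilt(sos, x - x.mean())
    analytic = hilbert(y)
    return np.angle(analytic) if extract == "phase" else np.abs(analytic)


def tort_mi(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18) -> PACResult:
    """Tort modulation index: normalized KL divergence of the phase-binned
    amplitude distribution from uniform.

    MI = 0 for amplitude independent of phase; MI -> 1 as the amplitude
    concentrates in a single phase bin.  Invariant under positive rescaling
    of the amplitude.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("empty phase bins: insufficient or degenerate data")
    means = sums / counts
    total = means.sum()
    if total <= 0:
        mi = 0.0
        p = np.full(n_bins, 1.0 / n_bins)
    else:
        p = means / total
        nz = p > 0
        mi = float(np.sum(p[nz] * np.log(p[nz] * n_bins)) / np.log(n_bins))
    return PACResult(phase_band=(np.nan, np.nan), amp_band=(np.nan, np.nan),
                     n_bins=n_bins, mi=mi, bin_mean_amplitudes=means)


def pac_from_timeseries(
    ts: TimeSeries,
    phase_band: tuple,
    amp_band: tuple = (30.0, 100.0),
    phase_channel: str = "vP1",
    amp_channel: str = "vP2",
    n_bins: int = 18,
) -> PACResult:
    """MI between the phase of one channel and the envelope of another."""
    phase = bandpass_phase_amp(ts, phase_band, "phase", channel=phase_channel)
    amp = bandpass_phase_amp(ts, amp_band, "amplitude", channel=amp_channel)
    res = tort_mi(phase, amp, n_bins=n_bins)
    return PACResult(phase_band=tuple(phase_band), amp_band=tuple(amp_band),
                     n_bins=n_bins, mi=res.mi,
                     bin_mean_amplitudes=res.bin_mean_amplitudes)


# --------------------------------------------------------------------------- #
# Lyapunov exponents
# --------------------------------------------------------------------------- #


def benettin_les(
    params: ModelParams,
    t_transient: float = 20.0,
    t_accumulate: float = 200.0,
    renorm_interval: float = 0.1,
    dt: float = 1e-4,
    initial: np.ndarray | None = None,
    n_blocks: int = 10,
) -> LyapunovPair:
    """Two largest Lyapunov exponents of the model by the Benettin method.

    ``convergence_error`` is the standard deviation of per-block estimates of
    lambda1 over ``n_blocks`` equal subdivisions of the accumulation window.
    """
    y0 = np.zeros(10) if initial is None else np.asarray(initial, dtype=float)
    p = params.as_vector()
    n_trans = int(round(t_transient / dt))
    ren_steps = max(1, int(round(renorm_interval / dt)))
    n_ren = int(round(t_accumulate / (ren_steps * dt)))
    log1, log2, y_end = _fast.benettin_increments(y0, p, dt, n_trans, n_ren, ren_steps)
    if not np.all(np.isfinite(y_end)):
        raise RuntimeError("trajectory blew up during Lyapunov accumulation")
    span = ren_steps * dt
    l1 = float(np.sum(log1) / (n_ren * span))
    l2 = float(np.sum(log2) / (n_ren * span))
    blocks = np.array_split(log1, n_blocks)
    block_l1 = np.array([b.sum() / (len(b) * span) for b in blocks if len(b)])
    err = float(np.std(block_l1))
    if l2 > l1:
        l1, l2 = l2, l1
    return LyapunovPair(lambda1=l1, lambda2=l2, convergence_error=err)


def classify_regime(le: LyapunovPair, tol: float = LE_ZERO_TOL) -> str:
    """Map (lambda1, lambda2) to a regime label.

    chaotic: lambda1 > tol; steady: lambda1 < -tol; periodic: lambda1 ~ 0 and
    lambda2 < -tol; quasiperiodic: both within tol of zero.
    """
    l1, l2 = le.lambda1, le.lambda2
    if l1 > tol:
        return "chaotic"
    if l1 < -tol:
        return "steady"
    if l2 < -tol:
        return "periodic"
    return "quasiperiodic"


def regime_map(
    params: ModelParams,
    phi1_grid,
    phi2_grid,
    t_transient: float = 20.0,
    t_accumulate: float = 200.0,
    tol: float = LE_ZERO_TOL,
) -> RegimeMap:
    """Benettin exponents and regime label per cell of a rectangular grid.

    Deterministic for fixed settings; cells whose trajectory blows up are
    labeled "invalid".
    """
    p1 = np.asarray(phi1_grid, dtype=float)
    p2 = np.asarray(phi2_grid, dtype=float)
    labels = np.empty((len(p2), len(p1)), dtype=object)
    L1 = np.full((len(p2), len(p1)), np.nan)
    L2 = np.full((len(p2), len(p1)), np.nan)
    for j, b in enumerate(p2):
        for i, a in enumerate(p1):
            pr = params.with_inputs(float(a), float(b))
            try:
                le = benettin_les(pr, t_transient=t_transient, t_accumulate=t_accumulate)
            except RuntimeError:
                labels[j, i] = "invalid"
                continue
            L1[j, i] = le.lambda1
            L2[j, i] = le.lambda2
            labels[j, i] = classify_regime(le, tol=tol)
    return RegimeMap(phi1=p1, phi2=p2, labels=labels, lambda1=L1, lambda2=L2)
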