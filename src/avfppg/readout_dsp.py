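"""Software emulation of the PPG readout chain.

Mirrors, in software, what the acquisition front end does to a raw
photocurrent: heart-rate estimation, a heart-rate-adaptive fourth-order
band-pass filter, programmable-gain scaling into a modeled ADC, beat
segmentation at the pulse feet, and per-beat perfusion-index (AC/DC)
extraction.  Filtering is zero-phase (forward-backward) by default since
the analysis is offline; set ``causal=True`` to emulate the causal
hardware path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DomainError, EstimationError, InsufficientSignalError

__all__ = [
    "PPGWaveform",
    "FilterSpec",
    "BeatSeries",
    "estimate_heart_rate",
    "adaptive_filter_spec",
    "apply_bandpass",
    "extract_dc",
    "segment_beats",
    "compute_pi_extrema",
    "simulate_pga_adc",
    "extract_features",
]


@dataclass(frozen=True)
class PPGWaveform:
    """Uniformly sampled optical-intensity signal."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise DomainError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise DomainError("waveform needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise DomainError("waveform contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: fixed order 4, Butterworth by default."""

    f_lo: float
    f_hi: float
    order: int = 4
    family: str = "butter"

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigError(f"need 0 < f_lo < f_hi, got {self.f_lo}, {self.f_hi}")
        if self.order != 4:
            raise ConfigError("filter order is fixed at 4")


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat measurements between successive pulse feet.

    ``boundaries`` holds the foot sample indices (len = n_beats + 1);
    artifact beats are excluded from the per-beat arrays but their count
    is kept in ``n_rejected``.
    """

    boundaries: np.ndarray
    ac_amplitude: np.ndarray
    dc_level: np.ndarray
    pi: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.boundaries) <= 0):
            raise DomainError("beat boundaries must be strictly increasing")
        if np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise DomainError("per-beat PI must lie in (0, 1)")

    @property
    def n_beats(self) -> int:
        return int(self.pi.size)


# ---------------------------------------------------------------------------
# heart rate and adaptive filtering
# ---------------------------------------------------------------------------

_HR_BAND = (0.5, 3.0)  # Hz searched for the cardiac peak


def estimate_heart_rate(w: PPGWaveform) -> float:
    """Dominant cardiac periodicity in bpm.

    Windowed FFT of the detrended signal; the spectral peak in the
    0.5-3 Hz band is refined by parabolic interpolation on log magnitude.
    """
    if w.duration < 5.0:
        raise EstimationError("need at least 5 s of signal to estimate heart rate")
    x = w.samples - np.mean(w.samples)
    if np.allclose(x, 0.0):
        raise EstimationError("constant signal; no cardiac component")
    n = x.size
    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(x * win))
    freqs = np.fft.rfftfreq(n, d=1.0 / w.fs)
    band = (freqs >= _HR_BAND[0]) & (freqs <= _HR_BAND[1])
    if not np.any(band):
        raise EstimationError("sampling too coarse for the cardiac band")
    mags = spec[band]
    noise_floor = np.median(mags)
    k_band = int(np.argmax(mags))
    if mags[k_band] < 5.0 * noise_floor:
        raise EstimationError("no spectral peak above the noise floor in 0.5-3 Hz")
    k = int(np.flatnonzero(band)[k_band])
    f_peak = freqs[k]
    if 0 < k < freqs.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        # parabolic refinement on log magnitude
        la, lb, lc = np.log(spec[k - 1 : k + 2])
        denom = la - 2.0 * lb + lc
        if denom != 0:
            delta = 0.5 * (la - lc) / denom
            f_peak = freqs[k] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    hr = float(f_peak * 60.0)
    return float(np.clip(hr, 30.0, 180.0))


def adaptive_filter_spec(hr_bpm: float) -> FilterSpec:
    """Heart-rate-adapted band-pass cutoffs.

    Low cutoff tracks half the cardiac frequency, high cutoff its eighth
    harmonic, each clipped to the hardware's fixed range (0.2-0.8 Hz and
    5-10 Hz).
    """
    if not 30.0 <= hr_bpm <= 180.0:
        raise DomainError(f"heart rate {hr_bpm} bpm outside [30, 180]")
    hr_hz = hr_bpm / 60.0
    f_lo = float(np.clip(0.5 * hr_hz, 0.2, 0.8))
    f_hi = float(np.clip(8.0 * hr_hz, 5.0, 10.0))
    return FilterSpec(f_lo=f_lo, f_hi=f_hi)


def _design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.f_hi >= fs / 2:
        raise ConfigError(
            f"high cutoff {spec.f_hi} Hz at or above Nyquist for fs={fs} Hz"
        )
    return sps.butter(
        spec.order, [spec.f_lo, spec.f_hi], btype="bandpass", fs=fs, output="sos"
    )


def apply_bandpass(
    w: PPGWaveform, spec: FilterSpec, *, causal: bool = False
) -> PPGWaveform:
    """Band-pass the waveform; returns the AC component.

    Zero-phase (forward-backward, order doubled in effect) unless
    ``causal`` is set.
    """
    sos = _design_sos(spec, w.fs)
    if causal:
        out = sps.sosfilt(sos, w.samples)
    else:
        out = sps.sosfiltfilt(sos, w.samples)
    return PPGWaveform(samples=np.asarray(out), fs=w.fs, t0=w.t0)


def extract_dc(w: PPGWaveform, hr_bpm: float) -> np.ndarray:
    """Quasi-static (DC) level: moving average over one beat period.

    Reflect padding at the edges; output has the input length.
    """
    window = int(round(w.fs * 60.0 / hr_bpm))
    if window < 1:
        window = 1
    if window > w.samples.size:
        raise DomainError("beat-period window longer than the signal")
    padded = np.pad(w.samples, (window // 2, window - window // 2), mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: w.samples.size]


# ---------------------------------------------------------------------------
# beat segmentation and perfusion index
# ---------------------------------------------------------------------------


def segment_beats(
    ac: PPGWaveform,
    hr_bpm: float,
    dc: np.ndarray | None = None,
    *,
    trim_edges: int = 0,
) -> BeatSeries:
    """Delimit beats at successive pulse feet of the filtered signal.

    Feet are prominent local minima of the AC component with a
    refractory distance of 0.6 nominal periods.  Beats whose length
    falls outside [0.5, 2] times the nominal period, or whose amplitude
    is implausible against the cohort of beats (outside [0.25, 4] times
    the median AC amplitude), are flagged artifact and excluded.
    ``trim_edges`` drops that many beats at each end of the record,
    where zero-phase filter transients distort amplitudes.
    """
    x = ac.samples
    if dc is None:
        dc = np.ones_like(x)
    if np.ptp(x) == 0:
        raise InsufficientSignalError("constant signal; no beats")
    nominal = ac.fs * 60.0 / hr_bpm
    # MAD-based prominence gate: robust even to a whole beat at 5x amplitude
    mad = float(np.median(np.abs(x - np.median(x))))
    if mad == 0:
        raise InsufficientSignalError("degenerate signal; no beats")
    feet, _ = sps.find_peaks(
        -x, distance=max(int(0.6 * nominal), 1), prominence=3.0 * mad
    )
    if trim_edges > 0 and feet.size > 2 * trim_edges + 1:
        feet = feet[trim_edges:-trim_edges]
    if feet.size < 4:
        raise InsufficientSignalError(
            f"found {max(feet.size - 1, 0)} beats; need at least 3 valid beats"
        )
    spans = np.diff(feet)
    length_ok = (spans >= 0.5 * nominal) & (spans <= 2.0 * nominal)

    amp = np.empty(spans.size)
    level = np.empty(spans.size)
    for i in range(spans.size):
        seg = x[feet[i] : feet[i + 1] + 1]
        # systolic peak minus the following trough: both belong to this
        # beat, so adjacent beats of different amplitude do not mix; the
        # last two samples sit on the next-beat junction and are excluded
        k = int(np.argmax(seg))
        stop = max(k + 1, seg.size - 2)
        amp[i] = seg[k] - float(np.min(seg[k:stop])) if k < stop else np.ptp(seg)
        level[i] = float(np.mean(dc[feet[i] : feet[i + 1] + 1]))
    med = np.median(amp[length_ok]) if np.any(length_ok) else np.median(amp)
    amp_ok = (amp >= 0.25 * med) & (amp <= 4.0 * med)
    valid = length_ok & amp_ok & (level > 0) & (amp > 0)
    if np.count_nonzero(valid) < 3:
        raise InsufficientSignalError(
            f"only {int(np.count_nonzero(valid))} plausible beats; need 3"
        )
    pi = amp[valid] / level[valid]
    boundaries = np.append(feet[:-1][valid], feet[1:][valid][-1])
    return BeatSeries(
        boundaries=boundaries,
        ac_amplitude=amp[valid],
        dc_level=level[valid],
        pi=pi,
        n_rejected=int(np.count_nonzero(~valid)),
    )


def compute_pi_extrema(beats: BeatSeries) -> tuple[float, float]:
    """(PI_max, PI_min) over the valid beats."""
    if beats.n_beats < 3:
        raise InsufficientSignalError("need at least 3 valid beats")
    return float(np.max(beats.pi)), float(np.min(beats.pi))


# ---------------------------------------------------------------------------
# PGA / ADC emulation
# ---------------------------------------------------------------------------


def simulate_pga_adc(
    w: PPGWaveform, bits: int = 16, vref: float = 3.3
) -> tuple[PPGWaveform, float]:
    """Gain the signal into [0.05, 0.95]*vref and quantize to 2**bits levels.

    Returns the de-quantized waveform (in volts) and the gain applied.
    """
    if not 8 <= bits <= 24:
        raise ConfigError(f"ADC resolution {bits} bits outside [8, 24]")
    span = float(np.ptp(w.samples))
    if span == 0:
        raise DomainError("zero-span input; PGA gain undefined")
    gain = 0.9 * vref / span
    scaled = (w.samples - np.min(w.samples)) * gain + 0.05 * vref
    levels = 2**bits - 1
    codes = np.round(scaled / vref * levels)
    quantized = codes / levels * vref
    return PPGWaveform(samples=quantized, fs=w.fs, t0=w.t0), gain


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def extract_features(
    w: PPGWaveform,
    *,
    adc_bits: int | None = None,
    vref: float = 3.3,
    causal: bool = False,
) -> dict[str, float]:
    """Run the whole chain: HR -> adaptive filter -> beats -> PI extrema.

    Returns ``{"pi_max", "pi_min", "hr", "n_beats", "n_rejected"}``.
    """
    if adc_bits is not None:
        # pass through the gain/quantize stage, then de-embed the known
        # gain and offset so AC and DC keep their physical ratio
        lo = float(np.min(w.samples))
        q, gain = simulate_pga_adc(w, bits=adc_bits, vref=vref)
        w = PPGWaveform(
            samples=(q.samples - 0.05 * vref) / gain + lo, fs=w.fs, t0=w.t0
        )
    hr = estimate_heart_rate(w)
    spec = adaptive_filter_spec(hr)
    ac = apply_bandpass(w, spec, causal=causal)
    dc = extract_dc(w, hr)
    beats = segment_beats(ac, hr, dc=dc, trim_edges=2)
    pi_max, pi_min = compute_pi_extrema(beats)
    return {
        "pi_max": pi_max,
        "pi_min": pi_min,
        "hr": hr,
        "n_beats": float(beats.n_beats),
        "n_rejected": float(beats.n_rejected),
    }
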