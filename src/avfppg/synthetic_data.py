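"""Synthetic cohorts and raw PPG waveforms.

Subjects are generated through the hemodynamic forward model: a latent
stenosis level and vessel geometry are drawn, the consistent pulsatile
diameters follow from the wall mechanics, and the observable features
(PI extrema, SpO2, pressures, HR) are computed exactly before optional
multiplicative measurement noise is added.  With zero noise the feature
-> DOS/BFV inverse maps recover the latent truths to round-off, which is
what makes every downstream module testable without real data.

Waveforms are pulse trains of a two-Gaussian beat template (systolic
peak plus dicrotic bump), mean-free per beat so the programmed per-beat
AC/DC ratio is exact, riding on a large DC level with optional mains
interference, baseline drift and white noise.

All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hemodynamics as hd
from .classify.features import (
    BFV_THRESHOLD_ML_MIN,
    DOS_THRESHOLD_PCT,
    FeatureVector,
    LabeledSubject,
)
from .errors import DomainError, GenerationError
from .readout_dsp import PPGWaveform

__all__ = ["CohortSpec", "WaveformSpec", "sample_cohort", "sample_waveform"]


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic hemodialysis cohort.

    ``control`` picks which task's class prevalence is enforced by the
    generator ('dos' or 'bfv'); the other task's labels emerge from the
    latent physiology.  The stenosis mixture components
    ``dos_range_healthy``/``dos_range_diseased`` leave a gap around the
    30% decision threshold by default; narrowing the gap lowers class
    separability.
    """

    n_subjects: int
    seed: int
    dos_positive_prevalence: float = 45.0 / 74.0
    bfv_positive_prevalence: float = 61.0 / 79.0
    control: str = "dos"
    d_range: tuple[float, float] = (0.45, 0.75)  # healthy lumen diameter, cm
    # Young's modulus defaults to the calibration value (a point range) so
    # that the feature -> DOS/BFV inverse closes exactly; widening the range
    # injects model mismatch the inverse cannot see.
    e_range: tuple[float, float] = (2.0e7, 2.0e7)
    sbp_range: tuple[float, float] = (100.0, 160.0)
    dbp_range: tuple[float, float] = (60.0, 95.0)
    spo2_range: tuple[float, float] = (0.94, 0.99)
    hr_range: tuple[float, float] = (50.0, 110.0)
    dos_range_healthy: tuple[float, float] = (0.0, 25.0)
    dos_range_diseased: tuple[float, float] = (35.0, 80.0)
    noise_sd: float = 0.02  # relative, multiplicative
    calibration: hd.CalibrationConstants = field(
        default_factory=hd.CalibrationConstants
    )
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise DomainError("n_subjects must be non-negative")
        for p in (self.dos_positive_prevalence, self.bfv_positive_prevalence):
            if not 0.0 < p < 1.0:
                raise DomainError("prevalences must lie in (0, 1)")
        if self.control not in ("dos", "bfv"):
            raise DomainError("control must be 'dos' or 'bfv'")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        for name in ("d_range", "e_range", "sbp_range", "dbp_range",
                     "spo2_range", "hr_range", "dos_range_healthy",
                     "dos_range_diseased"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise DomainError(f"{name} must be ordered low <= high")


@dataclass(frozen=True)
class WaveformSpec:
    """Shape of a raw synthetic PPG record."""

    duration: float = 20.0
    fs: float = 500.0
    dc_level: float = 1.0
    ac_fraction: float = 0.05  # cap on AC/DC; the true ratio is the subject PI
    mains_freq: float = 60.0
    mains_amp: float = 0.0  # absolute, same units as dc_level
    drift_amp: float = 0.0
    drift_period: float = 10.0
    noise_sd: float = 0.0  # absolute white-noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ac_fraction >= 0.1:
            raise DomainError("ac_fraction must stay below 0.1 (PPG AC << DC)")
        if self.mains_freq not in (50.0, 60.0):
            raise DomainError("mains frequency must be 50 or 60 Hz")
        if self.fs <= 2.0 * self.mains_freq:
            raise DomainError("fs must exceed twice the mains frequency")
        if self.duration <= 0 or self.dc_level <= 0:
            raise DomainError("duration and dc_level must be positive")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _draw_subject(
    spec: CohortSpec, rng: np.random.Generator, healthy_dos: bool
) -> dict[str, float]:
    """One latent draw pushed through the exact forward model."""
    dos_lo, dos_hi = (
        spec.dos_range_healthy if healthy_dos else spec.dos_range_diseased
    )
    dos = float(rng.uniform(dos_lo, dos_hi))
    D = float(rng.uniform(*spec.d_range))
    d = D * float(np.sqrt(1.0 - dos / 100.0))
    sbp = float(rng.uniform(*spec.sbp_range))
    dbp = float(rng.uniform(*spec.dbp_range))
    if sbp - dbp < 20.0:  # keep a physiological pulse pressure
        sbp = dbp + 20.0 + float(rng.uniform(0.0, 20.0))
    hemo = hd.Hemodynamics(sbp=sbp, dbp=dbp, hr_bpm=float(rng.uniform(*spec.hr_range)))
    spo2 = float(rng.uniform(*spec.spo2_range))
    cal = replace(spec.calibration, E=float(rng.uniform(*spec.e_range)))
    return hd.features_from_vessel(dos, d, hemo, spo2, cal)


def sample_cohort(spec: CohortSpec) -> list[LabeledSubject]:
    """Generate a cohort of labeled subjects.

    The prevalence of the controlled task is enforced per subject by
    bounded rejection; the generator raises if a requested class cannot
    be realized within the spec's parameter ranges.
    """
    rng = np.random.default_rng(spec.seed)
    prevalence = (
        spec.dos_positive_prevalence
        if spec.control == "dos"
        else spec.bfv_positive_prevalence
    )
    subjects: list[LabeledSubject] = []
    for i in range(spec.n_subjects):
        want_positive = bool(rng.random() < prevalence)
        feats = None
        for _ in range(spec.max_retries):
            # positive = passes the clinical check (low DOS / high BFV)
            cand = _draw_subject(spec, rng, healthy_dos=want_positive)
            if spec.control == "dos":
                ok = (cand["dos_pct"] < DOS_THRESHOLD_PCT) == want_positive
            else:
                ok = (cand["bfv_ml_min"] > BFV_THRESHOLD_ML_MIN) == want_positive
            if ok:
                feats = cand
                break
        if feats is None:
            raise GenerationError(
                f"could not realize a {'positive' if want_positive else 'negative'} "
                f"{spec.control} subject within {spec.max_retries} retries; "
                "the spec's parameter ranges make that class unreachable"
            )
        noisy = _add_feature_noise(feats, spec.noise_sd, rng)
        fv = FeatureVector(
            pi_max=noisy["pi_max"],
            pi_min=noisy["pi_min"],
            spo2=min(noisy["spo2"], 1.0),
            sbp=noisy["sbp"],
            dbp=noisy["dbp"],
            hr=noisy["hr"],
        )
        subjects.append(
            LabeledSubject(
                subject_id=f"S{i:04d}",
                features=fv,
                dos_label=1 if feats["dos_pct"] < DOS_THRESHOLD_PCT else -1,
                bfv_label=1 if feats["bfv_ml_min"] > BFV_THRESHOLD_ML_MIN else -1,
                dos_pct=feats["dos_pct"],
                bfv_ml_min=feats["bfv_ml_min"],
            )
        )
    return subjects


def _add_feature_noise(
    feats: dict[str, float], sd: float, rng: np.random.Generator
) -> dict[str, float]:
    if sd == 0.0:
        return dict(feats)
    out = dict(feats)
    for key in ("pi_max", "pi_min", "spo2", "sbp", "dbp", "hr"):
        out[key] = feats[key] * float(1.0 + sd * rng.standard_normal())
    # repair orderings the noise may have broken
    if out["pi_max"] <= out["pi_min"]:
        out["pi_max"], out["pi_min"] = (
            max(out["pi_max"], out["pi_min"]) * (1.0 + 1e-6),
            min(out["pi_max"], out["pi_min"]),
        )
    if out["sbp"] <= out["dbp"]:
        out["sbp"], out["dbp"] = (
            max(out["sbp"], out["dbp"]) + 1.0,
            min(out["sbp"], out["dbp"]),
        )
    return out


# ---------------------------------------------------------------------------
# waveform sampling
# ---------------------------------------------------------------------------


def _beat_template(n: int) -> np.ndarray:
    """Two-Gaussian beat (systolic peak + dicrotic bump), mean-free,
    peak-to-trough 1."""
    u = np.arange(n) / n
    g = np.exp(-0.5 * ((u - 0.30) / 0.09) ** 2) + 0.35 * np.exp(
        -0.5 * ((u - 0.62) / 0.12) ** 2
    )
    g = g - np.mean(g)
    return g / np.ptp(g)


def sample_waveform(
    subject: LabeledSubject, wspec: WaveformSpec
) -> tuple[PPGWaveform, dict]:
    """Raw PPG record for a subject plus the programmed ground truth.

    Per-beat AC/DC follows a slow sinusoidal trajectory between the
    subject's PI_min and PI_max (a respiratory-like modulation).  Returns
    the waveform and ``{"hr", "beat_pi", "pi_max", "pi_min"}`` where the
    PI extrema are those actually programmed into the record.
    """
    fv = subject.features
    if fv.pi_max >= wspec.ac_fraction:
        raise DomainError(
            f"subject PI_max {fv.pi_max:.3f} exceeds the AC cap {wspec.ac_fraction}"
        )
    rng = np.random.default_rng(wspec.seed)
    n = int(round(wspec.duration * wspec.fs))
    t = np.arange(n) / wspec.fs
    period = 60.0 / fv.hr
    samples_per_beat = int(round(period * wspec.fs))
    n_beats = n // samples_per_beat
    if n_beats < 4:
        raise DomainError("record too short for the subject's heart rate")
    template = _beat_template(samples_per_beat)

    # respiratory-like PI modulation over a 5-beat cycle
    k = np.arange(n_beats)
    mod = 0.5 * (1.0 + np.sin(2.0 * np.pi * k / 5.0))
    beat_pi = fv.pi_min + (fv.pi_max - fv.pi_min) * mod

    ac = np.zeros(n)
    for j in range(n_beats):
        start = j * samples_per_beat
        ac[start : start + samples_per_beat] = (
            wspec.dc_level * beat_pi[j] * template
        )
    sig = wspec.dc_level + ac
    if wspec.mains_amp:
        sig = sig + wspec.mains_amp * np.sin(2.0 * np.pi * wspec.mains_freq * t)
    if wspec.drift_amp:
        sig = sig + wspec.drift_amp * np.sin(
            2.0 * np.pi * t / wspec.drift_period
        )
    if wspec.noise_sd:
        sig = sig + wspec.noise_sd * rng.standard_normal(n)
    truth = {
        "hr": fv.hr,
        "beat_pi": beat_pi,
        "pi_max": float(np.max(beat_pi)),
        "pi_min": float(np.min(beat_pi)),
        "n_beats": n_beats,
    }
    return PPGWaveform(samples=sig, fs=wspec.fs), truth
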