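"""Synthetic vendor-unit EEG streams and cohorts with known ground truth.

Real recordings from the classroom platform are not redistributable, so
every downstream stage is exercised on synthetic data that emulates the
study conditions: a single prefrontal channel sampled at 512 Hz in signed
12-bit vendor units, a 1/f (pink) background, band-limited Gaussian
components in the canonical delta/theta/alpha/beta bands, 50 Hz mains
interference, and smooth biphasic blink transients large enough to trip
the 75 uV artifact gate.

Cohorts pair each subject's trace with a 0-10 task score whose rank
association with the subject's true beta gain is tunable (a Gaussian
copula drives the association), plus six Likert-scale mental-state
answers generated independently of beta power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ClippingError, EmptyCohortError, RawTrace, SessionAnnotation
from .dsp import DEFAULT_CONSTANTS, ConversionConstants

__all__ = [
    "BAND_EDGES",
    "SignalSpec",
    "CohortSpec",
    "CohortBundle",
    "generate_trace",
    "generate_cohort",
]

# generation bands; the beta definition matches the analysis band
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

RAW_MIN, RAW_MAX = -2048, 2047  # signed 12-bit vendor range


def _default_band_gains() -> dict[str, float]:
    # uV RMS per band; scalp beta amplitude is mostly below 30 uV so the
    # resting composite stays well under the 75 uV gate
    return {"delta": 6.0, "theta": 4.0, "alpha": 5.0, "beta": 3.0}


@dataclass
class SignalSpec:
    """Recipe for one synthetic trace.

    blink_schedule is a list of (onset_s, peak_uV, width_s) tuples; each
    blink is a Gaussian-windowed biphasic bump peaking at peak_uV.
    tones is a list of (freq_hz, amp_uV) pure sinusoids, useful for
    injecting a deterministic narrowband component (e.g. a 20 Hz probe in
    place of the stochastic beta component) in calibration runs.
    """

    duration_s: float
    fs: float = 512.0
    band_gains: dict[str, float] = field(default_factory=_default_band_gains)
    pink_gain: float = 8.0
    line_amp_uV: float = 2.0
    blink_schedule: list[tuple[float, float, float]] = field(default_factory=list)
    tones: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        gains = list(self.band_gains.values()) + [self.pink_gain, self.line_amp_uV]
        if any(g < 0 for g in gains):
            raise ValueError("all gains must be non-negative")
        unknown = set(self.band_gains) - set(BAND_EDGES)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")
        for onset, _, _ in self.blink_schedule:
            if not 0 <= onset < self.duration_s:
                raise ValueError("blink onsets must lie within [0, duration_s)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band: tuple[float, float], rms: float) -> np.ndarray:
    """Gaussian noise restricted to a frequency band, scaled to a target RMS."""
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(len(freqs))
    lo, hi = band
    amp[(freqs >= lo) & (freqs <= hi)] = 1.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    cur = x.std()
    return x * (rms / cur) if cur > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f-amplitude background noise with zero mean, scaled to a target RMS."""
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(len(freqs))
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x * (rms / x.std())


def _blink_pulse(t: np.ndarray, onset_s: float, peak_uV: float, width_s: float) -> np.ndarray:
    """Gaussian-windowed biphasic bump (derivative-of-Gaussian shape).

    The extrema sit at center +/- sigma with |value| = peak_uV, so a blink
    reliably exceeds an amplitude gate set below its peak.
    """
    center = onset_s + width_s / 2.0
    sigma = width_s / 4.0
    tau = (t - center) / sigma
    pulse = -tau * np.exp(0.5 * (1.0 - tau**2))  # max |.| = 1 at tau = -1
    return peak_uV * pulse


def generate_trace(spec: SignalSpec,
                   constants: ConversionConstants = DEFAULT_CONSTANTS,
                   subject_id: str = "S00") -> RawTrace:
    """Render a SignalSpec into quantized vendor units.

    The microvolt signal is the sum of pink background, band-limited
    Gaussian components, the mains sinusoid and blink pulses; it is then
    divided by the per-unit microvolt step, rounded, and clipped to the
    signed 12-bit range.  If any single component alone would clip more
    than 1% of samples the spec is rejected with the offending component
    named.

    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs

    components: dict[str, np.ndarray] = {}
    components["pink"] = _pink_noise(rng, n, spec.fs, spec.pink_gain)
    for band in ("delta", "theta", "alpha", "beta"):  # fixed order: reproducibility
        gain = spec.band_gains.get(band, 0.0)
        components[band] = _band_limited_noise(rng, n, spec.fs, BAND_EDGES[band], gain)
    phase = rng.uniform(0, 2 * np.pi)
    components["line"] = spec.line_amp_uV * np.sin(2 * np.pi * 50.0 * t + phase)
    if spec.tones:
        components["tones"] = sum(
            amp * np.sin(2 * np.pi * freq * t) for freq, amp in spec.tones
        )
    blink = np.zeros(n)
    for onset, peak, width in spec.blink_schedule:
        blink += _blink_pulse(t, onset, peak, width)
    components["blink"] = blink

    step_uV = constants.microvolts_per_unit
    for name, comp in components.items():
        if name == "blink":
            continue  # blinks are supposed to be large; the gate handles them
        frac = np.mean(np.abs(comp / step_uV) > RAW_MAX)
        if frac > 0.01:
            raise ClippingError(
                f"component {name!r} would clip {frac:.1%} of samples; reduce its gain"
            )

    uv = sum(components.values())
    raw_float = uv / step_uV
    raw = np.clip(np.round(raw_float), RAW_MIN, RAW_MAX).astype(np.int32)
    n_clipped = int(np.sum((raw_float > RAW_MAX) | (raw_float < RAW_MIN)))
    return RawTrace(
        subject_id=subject_id,
        fs=spec.fs,
        samples=raw,
        seed=spec.seed,
        n_clipped=n_clipped,
        meta={"duration_s": spec.duration_s, "band_gains": dict(spec.band_gains),
              "pink_gain": spec.pink_gain, "line_amp_uV": spec.line_amp_uV,
              "n_blinks": len(spec.blink_schedule)},
    )


# six mental-state questions: (mean, sd) on the 1-5 Likert scale, chosen to
# resemble a motivated classroom (high interest/attention, low stress)
ANSWER_PROFILE = {
    "attention": (4.3, 0.5),
    "stress": (1.7, 0.6),
    "relaxation": (3.3, 0.8),
    "interest": (4.3, 0.5),
    "fatigue": (2.2, 0.7),
    "effort": (2.7, 0.9),
}


@dataclass
class CohortSpec:
    """Recipe for a cohort of subjects with a known beta-score association.

    target_assoc is the desired Spearman rank correlation between the true
    per-subject beta RMS gain and the task score; it is realised through a
    Gaussian copula (see generate_cohort).  score_noise_sd adds further
    independent measurement noise on the 0-10 score scale.
    """

    n_subjects: int
    target_assoc: float = 0.6
    score_noise_sd: float = 0.5
    pass_mark: float = 5.0
    seed: int = 0
    annotation: SessionAnnotation | None = None
    blink_rate_hz: float = 0.05
    beta_gain_median: float = 3.0
    beta_gain_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if abs(self.target_assoc) > 1:
            raise ValueError("|target_assoc| must be <= 1")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be non-negative")


@dataclass
class CohortBundle:
    """Generated cohort: traces, scores, answers and the ground truth."""

    traces: list[RawTrace]
    scores: np.ndarray
    answers: pd.DataFrame
    truth: np.ndarray  # per-subject beta RMS gain in uV
    annotation: SessionAnnotation

    @property
    def n_subjects(self) -> int:
        return len(self.traces)


def generate_cohort(cspec: CohortSpec,
                    constants: ConversionConstants = DEFAULT_CONSTANTS) -> CohortBundle:
    """Draw a cohort whose beta gains and scores share a known rank association.

    Per subject, a standard-normal z drives a log-normal beta RMS gain.
    The score's latent is a z + sqrt(1-a^2) e with e independent, where
    a = 2 sin(pi rho_s / 6) converts the requested Spearman rho_s into the
    Gaussian-copula correlation; the latent is mapped affinely onto the
    0-10 scale (mean 5.0, sd 2.3, matching a mid-difficulty task) with
    optional extra score noise, then clipped.  Mental-state answers are
    drawn independently of beta gain, so their correlations with measured
    beta power are null by construction.
    """
    if cspec.n_subjects == 0:
        raise EmptyCohortError("cannot generate a cohort of zero subjects")
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_subjects
    annotation = cspec.annotation or SessionAnnotation.standard_session()
    duration = annotation.end_s

    z_beta = rng.standard_normal(n)
    gains = cspec.beta_gain_median * np.exp(cspec.beta_gain_log_sd * z_beta)

    rho_s = cspec.target_assoc
    a = 2.0 * math.sin(math.pi * rho_s / 6.0)
    latent = a * z_beta + math.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n)
    scores = 5.0 + 2.3 * latent + rng.normal(0.0, cspec.score_noise_sd, n)
    scores = np.clip(scores, 0.0, 10.0)

    answers = pd.DataFrame({
        q: np.clip(rng.normal(mu, sd, n), 1.0, 5.0)
        for q, (mu, sd) in ANSWER_PROFILE.items()
    })
    answers.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])

    traces = []
    for i in range(n):
        n_blinks = rng.poisson(cspec.blink_rate_hz * duration)
        onsets = np.sort(rng.uniform(0.0, max(duration - 0.5, 0.1), n_blinks))
        blinks = [
            (float(o), float(rng.uniform(100.0, 200.0)), float(rng.uniform(0.25, 0.45)))
            for o in onsets
        ]
        spec = SignalSpec(
            duration_s=duration,
            band_gains={**_default_band_gains(), "beta": float(gains[i])},
            blink_schedule=blinks,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        traces.append(generate_trace(spec, constants, subject_id=f"S{i:03d}"))

    return CohortBundle(
        traces=traces,
        scores=scores,
        answers=answers,
        truth=gains,
        annotation=annotation,
    )
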