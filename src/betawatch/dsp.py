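"""Per-epoch processing chain: vendor units to total mean beta PSD.

The chain mirrors the acquisition platform's signal processor.  Each 2-s
epoch (1024 samples at 512 Hz) goes through

1. vendor-unit -> microvolt conversion (amplifier gain 2000, 4096-value
   ADC range, 1.8 V input voltage),
2. an amplitude artifact gate at 75 uV (blinks, motion),
3. Butterworth 3-40 Hz band-pass (zero-phase), linear detrend, z-score,
4. Welch PSD with Tukey(0.15)-tapered segments at 50% overlap,
5. beta-band (12-30 Hz) power integration.

Per subject, beta power is averaged over accepted epochs that lie fully
inside video-labelled segments, then min-max normalized across the cohort
to yield the [0, 1] attention index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .core import (
    ConfigError,
    DegenerateEpochError,
    EmptyBandError,
    Epoch,
    EpochLengthError,
    EpochStatus,
    NormalizationError,
    SessionAnnotation,
)

__all__ = [
    "ConversionConstants",
    "ProcessingConfig",
    "PSDSpectrum",
    "EpochRecord",
    "SubjectSummary",
    "raw_to_volts",
    "raw_to_microvolts",
    "microvolts_to_raw",
    "is_artifact",
    "preprocess",
    "welch_psd",
    "band_power",
    "process_epoch",
    "summarize_subject",
    "normalize_cohort",
]


@dataclass(frozen=True)
class ConversionConstants:
    """ADC/amplifier constants of the headset front-end."""

    input_voltage: float = 1.8
    value_range: int = 4096
    gain: float = 2000.0

    def __post_init__(self) -> None:
        if min(self.input_voltage, self.value_range, self.gain) <= 0:
            raise ValueError("conversion constants must be strictly positive")

    @property
    def volts_per_unit(self) -> float:
        return (self.input_voltage / self.value_range) / self.gain

    @property
    def microvolts_per_unit(self) -> float:
        return self.volts_per_unit * 1e6


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable parameters of the per-epoch chain.

    ``epoch_aggregate`` selects how accepted per-epoch beta powers are
    collapsed into the subject summary: ``"mean"`` (default; robust to
    unequal accepted-epoch counts after artifact rejection) or ``"sum"``.
    """

    fs: float = 512.0
    epoch_len: int = 1024
    artifact_threshold_uV: float = 75.0
    bandpass: tuple[float, float] = (3.0, 40.0)
    filter_order: int = 4
    tukey_fraction: float = 0.15
    welch_overlap: float = 0.5
    welch_segment_len: int = 256
    beta_band: tuple[float, float] = (12.0, 30.0)
    amplitude_range_uV: tuple[float, float] = (-100.0, 100.0)
    epoch_aggregate: str = "mean"

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        blo, bhi = self.beta_band
        if not (lo <= blo < bhi <= hi):
            raise ConfigError("beta band must lie inside the band-pass range")
        if not 0 < self.welch_overlap < 1:
            raise ConfigError("welch_overlap must be in (0, 1)")
        if self.epoch_len != round(2 * self.fs):
            raise ConfigError("epoch_len must equal two seconds of samples")
        if self.welch_segment_len > self.epoch_len:
            raise ConfigError("welch_segment_len exceeds epoch length")
        if self.epoch_aggregate not in ("mean", "sum"):
            raise ConfigError("epoch_aggregate must be 'mean' or 'sum'")


@dataclass
class PSDSpectrum:
    """One-sided Welch PSD of a processed epoch."""

    freqs: np.ndarray
    power: np.ndarray
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class EpochRecord:
    """Outcome of processing one epoch."""

    index: int
    start_s: float
    status: EpochStatus
    beta_power: float | None = None


@dataclass
class SubjectSummary:
    """Per-subject attention summary with full epoch accounting."""

    subject_id: str
    per_epoch_beta: np.ndarray
    n_epochs_total: int
    n_rejected_artifact: int
    n_rejected_degenerate: int
    n_excluded_by_mask: int
    total_mean_beta: float
    valid: bool = True
    normalized_beta: float | None = None
    epoch_records: list[EpochRecord] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.per_epoch_beta)


def raw_to_volts(raw, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Convert vendor units to volts: raw x (input_voltage/value_range)/gain."""
    return np.asarray(raw, dtype=float) * constants.volts_per_unit


def raw_to_microvolts(raw, constants: ConversionConstants = DEFAULT_CONSTANTS):
    return np.asarray(raw, dtype=float) * constants.microvolts_per_unit


def microvolts_to_raw(uv, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Inverse conversion (float vendor units, not yet quantized)."""
    return np.asarray(uv, dtype=float) / constants.microvolts_per_unit


def is_artifact(epoch_uV, threshold_uV: float = 75.0, epoch_len: int | None = None) -> bool:
    """Amplitude gate: reject iff any |sample| strictly exceeds the threshold.

    The gate runs on converted microvolts *before* filtering -- band-pass
    filtering would smear a blink and could shrink it below threshold.
    """
    x = np.asarray(epoch_uV, dtype=float)
    if epoch_len is not None and len(x) != epoch_len:
        raise EpochLengthError(f"expected {epoch_len} samples, got {len(x)}")
    return bool(np.max(np.abs(x)) > threshold_uV)


def _bandpass_sos(cfg: ProcessingConfig):
    return signal.butter(
        cfg.filter_order, cfg.bandpass, btype="bandpass", fs=cfg.fs, output="sos"
    )


def preprocess(epoch_uV, cfg: ProcessingConfig = ProcessingConfig()) -> np.ndarray:
    """Band-pass (zero-phase), detrend and z-score one accepted epoch.

    Raises
    ------
    DegenerateEpochError
        If the epoch is constant (zero variance) and cannot be z-scored.
    """
    x = np.asarray(epoch_uV, dtype=float)
    if len(x) != cfg.epoch_len:
        raise EpochLengthError(f"expected {cfg.epoch_len} samples, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateEpochError("constant epoch has no variance")
    x = signal.sosfiltfilt(_bandpass_sos(cfg), x)
    x = signal.detrend(x, type="linear")
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateEpochError("epoch variance vanished after filtering")
    return (x - x.mean()) / sd


def welch_psd(processed, cfg: ProcessingConfig = ProcessingConfig(), epoch_index: int = 0) -> PSDSpectrum:
    """Welch PSD: Tukey-tapered overlapping segments, averaged periodograms."""
    x = np.asarray(processed, dtype=float)
    if cfg.welch_segment_len > len(x):
        raise ConfigError("welch_segment_len exceeds epoch length")
    freqs, power = signal.welch(
        x,
        fs=cfg.fs,
        window=("tukey", cfg.tukey_fraction),
        nperseg=cfg.welch_segment_len,
        noverlap=int(round(cfg.welch_overlap * cfg.welch_segment_len)),
        detrend=False,
    )
    return PSDSpectrum(freqs=freqs, power=power, epoch_index=epoch_index)


def band_power(spectrum: PSDSpectrum, band: tuple[float, float] = (12.0, 30.0),
               closed: str = "both") -> float:
    """Integrate PSD over a band: sum(power) x bin width.

    ``closed`` controls edge inclusion: ``"both"`` (default, the headline
    beta statistic uses the closed interval [12, 30]), ``"right"`` or
    ``"left"`` for partition arithmetic.
    """
    lo, hi = band
    f = spectrum.freqs
    if closed == "both":
        mask = (f >= lo) & (f <= hi)
    elif closed == "right":
        mask = (f > lo) & (f <= hi)
    elif closed == "left":
        mask = (f >= lo) & (f < hi)
    else:
        raise ValueError("closed must be 'both', 'right' or 'left'")
    if not mask.any():
        raise EmptyBandError(f"no spectrum bins in band {band}")
    return float(np.sum(spectrum.power[mask]) * spectrum.df)


def process_epoch(epoch: Epoch, cfg: ProcessingConfig = ProcessingConfig(),
                  constants: ConversionConstants = DEFAULT_CONSTANTS) -> EpochRecord:
    """Run the full chain on one raw epoch, without annotation masking."""
    uv = raw_to_microvolts(epoch.raw, constants)
    lo, hi = cfg.amplitude_range_uV
    uv = np.clip(uv, lo, hi)
    if is_artifact(uv, cfg.artifact_threshold_uV, epoch_len=cfg.epoch_len):
        return EpochRecord(epoch.index, epoch.start_s, EpochStatus.REJECTED_ARTIFACT)
    try:
        processed = preprocess(uv, cfg)
    except DegenerateEpochError:
        return EpochRecord(epoch.index, epoch.start_s, EpochStatus.REJECTED_DEGENERATE)
    spectrum = welch_psd(processed, cfg, epoch_index=epoch.index)
    beta = band_power(spectrum, cfg.beta_band)
    return EpochRecord(epoch.index, epoch.start_s, EpochStatus.ACCEPTED, beta_power=beta)


def summarize_subject(
    epochs: list[Epoch],
    annotation: SessionAnnotation,
    cfg: ProcessingConfig = ProcessingConfig(),
    constants: ConversionConstants = DEFAULT_CONSTANTS,
    subject_id: str | None = None,
) -> SubjectSummary:
    """Summarize a subject: masked, artifact-gated mean beta power.

    Epochs not fully inside a video segment are excluded before the
    artifact gate so the exclusion counts are disjoint.  A subject whose
    kept set is empty is flagged invalid and later excluded from cohort
    normalization.
    """
    records: list[EpochRecord] = []
    betas: list[float] = []
    n_artifact = n_degenerate = n_masked = 0
    sid = subject_id or (epochs[0].subject_id if epochs else "unknown")
    for ep in epochs:
        if not annotation.contains_epoch(ep.start_s, ep.end_s(cfg.fs)):
            records.append(EpochRecord(ep.index, ep.start_s, EpochStatus.EXCLUDED_BY_MASK))
            n_masked += 1
            continue
        rec = process_epoch(ep, cfg, constants)
        records.append(rec)
        if rec.status is EpochStatus.REJECTED_ARTIFACT:
            n_artifact += 1
        elif rec.status is EpochStatus.REJECTED_DEGENERATE:
            n_degenerate += 1
        else:
            betas.append(rec.beta_power)
    beta_arr = np.asarray(betas, dtype=float)
    valid = len(betas) > 0
    if not valid:
        warnings.warn(f"subject {sid}: no accepted epochs; summary flagged invalid",
                      stacklevel=2)
        total = float("nan")
    elif cfg.epoch_aggregate == "sum":
        total = float(beta_arr.sum())
    else:
        total = float(beta_arr.mean())
    return SubjectSummary(
        subject_id=sid,
        per_epoch_beta=beta_arr,
        n_epochs_total=len(epochs),
        n_rejected_artifact=n_artifact,
        n_rejected_degenerate=n_degenerate,
        n_excluded_by_mask=n_masked,
        total_mean_beta=total,
        valid=valid,
        epoch_records=records,
    )


def normalize_cohort(summaries: list[SubjectSummary]) -> list[SubjectSummary]:
    """Min-max scale total mean beta to [0, 1] across valid subjects."""
    valid = [s for s in summaries if s.valid]
    if len(valid) < 2:
        raise NormalizationError("need at least two valid subjects to normalize")
    totals = np.array([s.total_mean_beta for s in valid])
    lo, hi = totals.min(), totals.max()
    if lo == hi:
        raise NormalizationError("all subject totals are equal; min-max undefined")
    out = []
    for s in summaries:
        if s.valid:
            out.append(replace(s, normalized_beta=float((s.total_mean_beta - lo) / (hi - lo))))
        else:
            out.append(replace(s, normalized_beta=None))
    return out


def segment_mean_betas(summary: SubjectSummary, annotation: SessionAnnotation,
                       cfg: ProcessingConfig = ProcessingConfig()) -> np.ndarray:
    """Mean accepted beta power per video segment (classifier features).

    Segments with no accepted epochs get the subject's overall mean so the
    feature vector stays complete.
    """
    vids = annotation.video_segments
    means = np.full(len(vids), np.nan)
    for i, seg in enumerate(vids):
        vals = [r.beta_power for r in summary.epoch_records
                if r.status is EpochStatus.ACCEPTED
                and r.start_s >= seg.start_s and r.start_s < seg.end_s]
        if vals:
            means[i] = float(np.mean(vals))
    if np.isnan(means).any():
        means = np.where(np.isnan(means), summary.total_mean_beta, means)
    return means
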