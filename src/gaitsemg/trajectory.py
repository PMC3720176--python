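"""Time normalization and ensemble averaging of envelope trajectories.

Each stride's envelope is resampled onto a fixed 100-point grid for the
full gait cycle and for stance and swing separately, so curves from strides
(and subjects) of different durations can be averaged pointwise and
compared. The grid is left-closed/right-open: point k sits at fraction
k/100 of the segment, so stance point 0 is heel strike, swing point 0 is
toe off, and concatenating the two phase curves introduces no duplicated
boundary sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .envelope import LinearEnvelope
from .gait import Stride

PHASES = ("cycle", "stance", "swing")


@dataclass
class NormalizedCurve:
    """Fixed-length time-normalized amplitude trajectory (microvolts)."""

    values: np.ndarray
    phase: str
    n_source_samples: int = 0
    muscle: str = ""
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if np.any(self.values < 0):
            raise ValueError("normalized amplitudes must be non-negative")


@dataclass
class EnsembleCurve:
    """Pointwise mean and sample SD of a set of normalized curves."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    level: str
    phase: str = ""
    muscle: str = ""
    subject: str = ""
    condition: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.level not in ("stride", "subject", "group"):
            raise ValueError(f"invalid ensemble level {self.level!r}")


@dataclass
class PhaseAmplitude:
    """Mean envelope amplitude over stance and over swing (microvolts)."""

    stance_mean: float
    swing_mean: float
    muscle: str = ""
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.stance_mean < 0 or self.swing_mean < 0:
            raise ValueError("phase-mean amplitudes must be non-negative")


def normalize_segment(
    envelope: LinearEnvelope,
    t_start: float,
    t_end: float,
    n_points: int = 100,
    phase: str = "cycle",
) -> NormalizedCurve:
    """Resample the envelope over [t_start, t_end) onto n_points points.

    Target times are ``t_k = t_start + (k / n_points) * (t_end - t_start)``
    for k = 0..n_points-1 (right-open grid); values come from linear
    interpolation of the uniformly sampled envelope.
    """
    if not t_start < t_end:
        raise ValueError("t_start must precede t_end")
    t_last = (envelope.samples.size - 1) / envelope.fs
    if t_start < 0 or t_end > t_last + 0.5 / envelope.fs:
        raise ValueError(
            f"segment [{t_start:.4f}, {t_end:.4f}] s outside the recording "
            f"span [0, {t_last:.4f}] s"
        )
    times = envelope.times
    in_seg = int(np.sum((times >= t_start) & (times < t_end)))
    if in_seg < 2:
        raise ValueError("segment must contain at least 2 envelope samples")
    targets = t_start + (np.arange(n_points) / n_points) * (t_end - t_start)
    values = np.interp(targets, times, envelope.samples)
    return NormalizedCurve(
        values=values, phase=phase, n_source_samples=in_seg,
        muscle=envelope.muscle, subject=envelope.subject,
        condition=envelope.condition,
    )


def stride_curves(
    envelope: LinearEnvelope, stride: Stride, n_points: int = 100
) -> tuple[NormalizedCurve, NormalizedCurve, NormalizedCurve]:
    """(cycle, stance, swing) normalized curves for one stride."""
    cycle = normalize_segment(envelope, stride.hs, stride.next_hs, n_points, "cycle")
    stance = normalize_segment(envelope, stride.hs, stride.to, n_points, "stance")
    swing = normalize_segment(envelope, stride.to, stride.next_hs, n_points, "swing")
    return cycle, stance, swing


def ensemble_average(
    curves: list[NormalizedCurve], level: str = "subject"
) -> EnsembleCurve:
    """Pointwise mean and sample SD (n-1) of same-phase curves."""
    if not curves:
        raise ValueError("no curves to average")
    phases = {c.phase for c in curves}
    if len(phases) > 1:
        raise ValueError(f"cannot average curves of mixed phases {sorted(phases)}")
    lengths = {c.values.size for c in curves}
    if len(lengths) > 1:
        raise ValueError("curves have unequal lengths")
    stack = np.stack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    first = curves[0]
    return EnsembleCurve(
        mean=mean, sd=sd, n=stack.shape[0], level=level, phase=first.phase,
        muscle=first.muscle, subject=first.subject, condition=first.condition,
    )


def group_average(subject_curves: list[EnsembleCurve]) -> EnsembleCurve:
    """Subject-weighted group ensemble: each subject's mean counts once.

    The SD is the between-subject sample SD of the subject means, ignoring
    how many strides each subject's own ensemble averaged.
    """
    if not subject_curves:
        raise ValueError("no subject ensembles to average")
    lengths = {c.mean.size for c in subject_curves}
    if len(lengths) > 1:
        raise ValueError("subject ensembles have unequal lengths")
    stack = np.stack([c.mean for c in subject_curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    first = subject_curves[0]
    return EnsembleCurve(
        mean=mean, sd=sd, n=stack.shape[0], level="group", phase=first.phase,
        muscle=first.muscle, condition=first.condition,
    )


def phase_mean_amplitude(envelope: LinearEnvelope, stride: Stride) -> PhaseAmplitude:
    """Time-domain mean of the envelope over stance and swing.

    Averages the original envelope samples with times in [hs, to) and
    [to, next_hs) — not the normalized curves — so unequal phase durations
    keep their natural sample weighting.
    """
    times = envelope.times
    stance_mask = (times >= stride.hs) & (times < stride.to)
    swing_mask = (times >= stride.to) & (times < stride.next_hs)
    if not stance_mask.any() or not swing_mask.any():
        raise ValueError("stride phases contain no envelope samples")
    return PhaseAmplitude(
        stance_mean=float(envelope.samples[stance_mask].mean()),
        swing_mean=float(envelope.samples[swing_mask].mean()),
        muscle=envelope.muscle, subject=envelope.subject,
        condition=envelope.condition,
    )


def resample_reference(
    percent: np.ndarray,
    amplitude: np.ndarray,
    n_points: int = 100,
    phase: str = "cycle",
) -> NormalizedCurve:
    """Resample a digitized reference trajectory onto the 100-point grid.

    Input is (percent-of-phase, amplitude) pairs of arbitrary length with
    non-decreasing percents spanning [0, 100] (1 percent-point tolerance at
    either end); output lands on the same left-closed grid as
    :func:`normalize_segment` so reference and measured curves align.
    """
    percent = np.asarray(percent, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if percent.size != amplitude.size or percent.size < 2:
        raise ValueError("reference needs >= 2 (percent, amplitude) pairs")
    if np.any(np.diff(percent) < 0):
        raise ValueError("reference percents must be non-decreasing")
    if percent[0] > 1.0 or percent[-1] < 99.0:
        raise ValueError(
            f"reference must span [0, 100] percent (got [{percent[0]:g}, "
            f"{percent[-1]:g}])"
        )
    targets = 100.0 * np.arange(n_points) / n_points
    values = np.interp(targets, percent, amplitude)
    return NormalizedCurve(values=values, phase=phase,
                           n_source_samples=percent.size)
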