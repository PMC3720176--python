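"""Linear-envelope extraction for surface EMG.

Raw sEMG is converted to a linear envelope in three steps: a bidirectional
(zero-lag) Butterworth high-pass to remove baseline drift and motion
artifact, full-wave rectification, and moving root-mean-square smoothing.
Defaults follow common clinical-gait practice: 10 Hz cut-off, 100 ms RMS
window, 2nd-order filter per pass (effective 4th order after the
forward-backward application).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import signal

logger = logging.getLogger("gaitsemg")

#: canonical muscle channel order: tibialis anterior, gastrocnemius
#: lateralis, vastus medialis, biceps femoris
MUSCLES = ("TA", "GM", "VM", "BF")

GROUPS = ("patient", "healthy")
CONDITIONS = ("DGO", "DGO_therapist", "treadmill")


class ParameterError(ValueError):
    """A filter/window parameter is outside its valid range."""


class SignalLengthError(ValueError):
    """The signal is too short for the requested operation."""


@dataclass
class EmgRecording:
    """A single-channel raw sEMG trace in microvolts.

    ``samples`` is a 1-D float array at sampling rate ``fs`` (Hz). The label
    fields identify where the trace came from; they are carried through the
    processing chain unchanged.
    """

    samples: np.ndarray
    fs: float
    muscle: str = ""
    subject: str = ""
    group: str = ""
    condition: str = ""
    leg: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class LinearEnvelope:
    """Rectified, RMS-smoothed amplitude trace on the original time base.

    ``provenance`` records the processing parameters (high-pass cut-off in
    Hz, RMS window in ms, filter order per pass) so results stay traceable.
    """

    samples: np.ndarray
    fs: float
    provenance: dict[str, Any] = field(default_factory=dict)
    muscle: str = ""
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be non-negative")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def highpass_zero_lag(
    recording: EmgRecording,
    cutoff: float = 10.0,
    order_per_pass: int = 2,
) -> EmgRecording:
    """Zero-lag Butterworth high-pass (forward-backward application).

    The filter is applied forward then backward, cancelling the phase shift;
    the effective magnitude response is the squared single-pass response
    (order ``2 * order_per_pass``). Output length equals input length; edges
    are handled by scipy's reflective padding inside ``sosfiltfilt``.
    """
    nyquist = recording.fs / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(
            f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}"
        )
    if order_per_pass < 1:
        raise ParameterError("order_per_pass must be >= 1")
    sos = signal.butter(order_per_pass, cutoff, btype="highpass", fs=recording.fs, output="sos")
    # sosfiltfilt pads with 3 * (n_sections * 2 + 1) samples per edge;
    # require twice that so the padded region never dominates the signal
    padlen = 2 * 3 * (sos.shape[0] * 2 + 1)
    if recording.samples.size <= padlen:
        raise SignalLengthError(
            f"signal of {recording.samples.size} samples is shorter than the "
            f"edge padding ({padlen} samples)"
        )
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return replace(recording, samples=filtered)


def rectify(recording: EmgRecording) -> EmgRecording:
    """Full-wave rectification: each sample replaced by its absolute value."""
    return replace(recording, samples=np.abs(recording.samples))


def _window_samples(window_ms: float, fs: float) -> int:
    return int(round(window_ms * fs / 1000.0))


def rms_envelope(recording: EmgRecording, window_ms: float = 100.0) -> LinearEnvelope:
    """Moving-RMS smoothing over a centered window.

    ``output[i] = sqrt(mean(x[j]**2))`` over a centered window of
    ``round(window_ms * fs / 1000)`` samples; the signal is reflection-padded
    (edge sample included) so output length equals input length. For an even
    window the centre sits half a sample early, i.e. the window covers
    ``(w-1)//2`` samples to the left and ``w//2`` to the right.
    """
    w = _window_samples(window_ms, recording.fs)
    n = recording.samples.size
    if w < 1:
        raise ParameterError(f"window of {window_ms} ms is shorter than one sample")
    if w > n:
        raise SignalLengthError(f"window of {w} samples exceeds signal length {n}")
    left, right = (w - 1) // 2, w // 2
    sq = np.pad(recording.samples**2, (left, right), mode="symmetric")
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    mean_sq = (csum[w:] - csum[:-w]) / w
    env = np.sqrt(np.maximum(mean_sq, 0.0))
    return LinearEnvelope(
        samples=env,
        fs=recording.fs,
        provenance={"window_ms": window_ms, "window_samples": w},
        muscle=recording.muscle,
        subject=recording.subject,
        group=recording.group,
        condition=recording.condition,
    )


def linear_envelope(
    recording: EmgRecording,
    cutoff: float = 10.0,
    window_ms: float = 100.0,
    order_per_pass: int = 2,
) -> LinearEnvelope:
    """Full chain: zero-lag high-pass, rectify, moving-RMS smoothing."""
    filtered = highpass_zero_lag(recording, cutoff=cutoff, order_per_pass=order_per_pass)
    env = rms_envelope(rectify(filtered), window_ms=window_ms)
    env.provenance = {
        "cutoff_hz": cutoff,
        "window_ms": window_ms,
        "order_per_pass": order_per_pass,
        "effective_order": 2 * order_per_pass,
    }
    return env
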