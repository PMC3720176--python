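"""Synthetic gait-sEMG cohorts with known ground truth.

The generator emulates the study design the analysis pipeline targets:
two groups (patients n=9, healthy n=8) walking roughly two minutes per
condition in three conditions (robot-assisted DGO walking, DGO with
therapist encouragement, unassisted treadmill), four muscles (TA, GM, VM,
BF) sampled at 2000 Hz, with gait events quantized to a 50 Hz video grid.

Signal model: amplitude-modulated white noise.  The raw trace is
``s(t) = template(phi(t)) * w(t)`` with ``w`` standard Gaussian white noise
and ``template`` a periodic activation profile (raised-cosine burst over a
baseline) indexed by gait-cycle phase ``phi`` in percent.  Because the RMS
of ``a * N(0,1)`` is ``a``, the pipeline's RMS linear envelope is an
unbiased estimator of the template, which makes every downstream stage
verifiable by parameter recovery.

Stance fractions are drawn once per subject from the group x condition
normal distribution (the study reports between-subject spreads), with a
small fixed per-stride jitter on top.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .envelope import CONDITIONS, GROUPS, MUSCLES, EmgRecording
from .gait import EventStructureError, GaitEventSeries

logger = logging.getLogger("gaitsemg")


# ---------------------------------------------------------------------------
# activation templates
# ---------------------------------------------------------------------------


class ActivationTemplate(BaseModel):
    """Periodic per-muscle activation profile over the gait cycle.

    Active on the phase window [onset_pct, offset_pct) percent of cycle
    (wrap-around permitted: offset < onset means the burst spans the cycle
    boundary, as for TA ~55-15%). Inside the window the envelope amplitude
    ramps as a raised cosine from ``baseline`` up to ``baseline + gain`` at
    the window midpoint; outside it stays at ``baseline``.
    """

    muscle: str
    onset_pct: float = Field(ge=0.0, lt=100.0)
    offset_pct: float = Field(ge=0.0, lt=100.0)
    gain: float = Field(ge=0.0)
    baseline: float = Field(gt=0.0)

    def window_length(self) -> float:
        """Active-window length in percent of cycle (0 for a point window)."""
        return (self.offset_pct - self.onset_pct) % 100.0

    def __call__(self, phi: np.ndarray | float) -> np.ndarray | float:
        """Envelope amplitude (microvolts) at gait-cycle phase percent phi."""
        phi = np.asarray(phi, dtype=float) % 100.0
        length = self.window_length()
        if length == 0.0 or self.gain == 0.0:
            out = np.full_like(phi, self.baseline)
            return out if out.ndim else float(out)
        u = (phi - self.onset_pct) % 100.0
        inside = u < length
        shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * u / length))
        out = np.where(inside, self.baseline + self.gain * shape, self.baseline)
        return out if out.ndim else float(out)


def make_activation_template(
    muscle: str,
    onset_pct: float,
    offset_pct: float,
    gain: float,
    baseline: float,
) -> ActivationTemplate:
    """Build a validated raised-cosine activation template."""
    if not (0.0 <= onset_pct < 100.0 and 0.0 <= offset_pct < 100.0):
        raise ValueError("onset_pct and offset_pct must lie in [0, 100)")
    if gain < 0:
        raise ValueError(f"gain must be non-negative, got {gain}")
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return ActivationTemplate(
        muscle=muscle,
        onset_pct=onset_pct,
        offset_pct=offset_pct,
        gain=gain,
        baseline=baseline,
    )


# Typical activation windows in percent of gait cycle (onset, offset):
# TA fires from pre-swing through loading (wraps the cycle boundary), GM in
# stance, VM from terminal swing into stance, BF from terminal swing into
# early stance.
ACTIVATION_WINDOWS: dict[str, tuple[float, float]] = {
    "TA": (55.0, 15.0),
    "GM": (15.0, 50.0),
    "VM": (75.0, 30.0),
    "BF": (85.0, 10.0),
}

#: per-muscle burst gain in the plain DGO condition (microvolts); the study
#: performed no MVC normalization, so the absolute scale is a free choice
BASE_GAINS: dict[str, float] = {"TA": 60.0, "GM": 45.0, "VM": 55.0, "BF": 40.0}
BASELINE_UV = 3.0

#: condition gain factors emulating the reported amplitude ordering
#: (therapist encouragement raises amplitudes most)
CONDITION_GAIN_FACTORS: dict[str, float] = {
    "DGO": 1.0,
    "DGO_therapist": 1.5,
    "treadmill": 1.3,
}

#: group x condition stance-fraction distributions (mean, SD) on (0, 1)
STANCE_FRACTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "patient": {"DGO": (0.57, 0.02), "DGO_therapist": (0.56, 0.04), "treadmill": (0.74, 0.05)},
    "healthy": {"DGO": (0.54, 0.03), "DGO_therapist": (0.53, 0.02), "treadmill": (0.67, 0.04)},
}


def default_templates() -> dict[str, dict[str, ActivationTemplate]]:
    """Per-condition, per-muscle activation templates with default gains."""
    return {
        cond: {
            m: make_activation_template(
                m,
                ACTIVATION_WINDOWS[m][0],
                ACTIVATION_WINDOWS[m][1],
                BASE_GAINS[m] * factor,
                BASELINE_UV,
            )
            for m in MUSCLES
        }
        for cond, factor in CONDITION_GAIN_FACTORS.items()
    }


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------


class GaussianSpec(BaseModel):
    """Mean and SD of a normal distribution."""

    mean: float
    sd: float = Field(ge=0.0)


class SimulationConfig(BaseModel):
    """Full description of a simulated cohort; (config, seed) fixes every output."""

    n_subjects: dict[str, int] = Field(
        default_factory=lambda: {"patient": 9, "healthy": 8}
    )
    conditions: list[str] = Field(default_factory=lambda: list(CONDITIONS))
    strides_per_subject: int = 25
    fs_emg: float = 2000.0
    fs_video: float = 50.0
    stride_duration: GaussianSpec = Field(
        default_factory=lambda: GaussianSpec(mean=2.4, sd=0.1)
    )
    stride_jitter_sd: float = 0.005  # per-stride stance-fraction SD
    stance_fraction: dict[str, dict[str, GaussianSpec]] = Field(
        default_factory=lambda: {
            g: {c: GaussianSpec(mean=m, sd=s) for c, (m, s) in d.items()}
            for g, d in STANCE_FRACTIONS.items()
        }
    )
    templates: dict[str, dict[str, ActivationTemplate]] = Field(
        default_factory=default_templates
    )
    noise: str = "amplitude_modulated_gaussian"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.fs_emg <= 0 or self.fs_video <= 0:
            raise ValueError("sampling rates must be positive")
        if self.strides_per_subject < 0:
            raise ValueError("strides_per_subject must be non-negative")
        for g, conds in self.stance_fraction.items():
            for c, spec in conds.items():
                lo, hi = spec.mean - 3 * spec.sd, spec.mean + 3 * spec.sd
                if not (0.0 < lo and hi < 1.0):
                    raise ValueError(
                        f"stance fraction for {g}/{c} must satisfy "
                        f"0 < mean +/- 3 SD < 1, got ({lo:.3f}, {hi:.3f})"
                    )
        for cond in self.conditions:
            tpls = self.templates.get(cond)
            if tpls is None or any(m not in tpls for m in MUSCLES):
                raise ValueError(f"condition {cond!r} lacks templates for all muscles")
        return self

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def config_schema() -> dict:
    """JSON schema the simulate command validates configs against."""
    return SimulationConfig.model_json_schema()


# ---------------------------------------------------------------------------
# subject-level simulation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-subject generating parameters and exact (unquantized) events."""

    subject: str
    group: str
    condition: str
    subject_stance_fraction: float
    stride_stance_fractions: np.ndarray
    stride_durations: np.ndarray
    heel_strikes_exact: np.ndarray
    toe_offs_exact: np.ndarray
    templates: dict[str, ActivationTemplate] = dc_field(default_factory=dict)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, low: float, high: float) -> np.ndarray:
    """Normal draws truncated to (low, high) by redraw."""
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out >= high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return out


def quantize_events(events: GaitEventSeries, fs_video: float) -> GaitEventSeries:
    """Snap each event time to the nearest video frame (multiple of 1/fs).

    Raises an error naming the stride index if two consecutive events
    collapse onto the same frame (the stride becomes degenerate at the
    annotation resolution).
    """
    if fs_video <= 0:
        raise ValueError("fs_video must be positive")
    hs_q = np.round(events.heel_strikes * fs_video) / fs_video
    to_q = np.round(events.toe_offs * fs_video) / fs_video
    # interleave and check strict ordering survives quantization
    merged = np.empty(hs_q.size + to_q.size)
    merged[0::2] = hs_q
    merged[1::2] = to_q[: merged[1::2].size]
    bad = np.flatnonzero(np.diff(merged) <= 0)
    if bad.size:
        stride_idx = int(bad[0]) // 2
        raise EventStructureError(
            f"events of stride {stride_idx} collide on the "
            f"{fs_video:g} Hz frame grid (t={merged[bad[0]]:.4f} s)"
        )
    return GaitEventSeries(heel_strikes=hs_q, toe_offs=to_q, source_rate=fs_video)


def simulate_gait_events(
    config: SimulationConfig,
    group: str,
    condition: str,
    rng: np.random.Generator,
    subject: str = "",
) -> tuple[GaitEventSeries, GroundTruth]:
    """Draw one subject's exact gait events and stance-fraction truth."""
    spec = config.stance_fraction[group][condition]
    n = config.strides_per_subject
    durations = _truncated_normal(
        rng, config.stride_duration.mean, config.stride_duration.sd, n,
        low=0.05, high=np.inf,
    )
    subject_frac = float(
        _truncated_normal(rng, spec.mean, spec.sd, 1, low=0.0, high=1.0)[0]
    )
    if config.stride_jitter_sd > 0:
        fracs = _truncated_normal(
            rng, subject_frac, config.stride_jitter_sd, n, low=0.0, high=1.0
        )
    else:
        fracs = np.full(n, subject_frac)
    hs = np.concatenate(([0.0], np.cumsum(durations)))
    to = hs[:-1] + fracs * durations
    events = GaitEventSeries(heel_strikes=hs, toe_offs=to, source_rate=None)
    truth = GroundTruth(
        subject=subject,
        group=group,
        condition=condition,
        subject_stance_fraction=subject_frac,
        stride_stance_fractions=fracs,
        stride_durations=durations,
        heel_strikes_exact=hs,
        toe_offs_exact=to,
        templates=dict(config.templates[condition]),
    )
    return events, truth


def cycle_phase(times: np.ndarray, heel_strikes: np.ndarray,
                durations: np.ndarray) -> np.ndarray:
    """Gait-cycle phase in percent at each time, given exact stride bounds."""
    idx = np.clip(np.searchsorted(heel_strikes, times, side="right") - 1, 0,
                  durations.size - 1)
    return 100.0 * (times - heel_strikes[idx]) / durations[idx]


def simulate_subject(
    config: SimulationConfig,
    group: str,
    condition: str,
    subject_id: str,
    rng: np.random.Generator,
) -> tuple[dict[str, EmgRecording], GaitEventSeries, GroundTruth]:
    """Simulate one subject: raw sEMG per muscle, quantized events, truth.

    The recording spans all ``strides_per_subject`` strides; the returned
    event series is quantized to the video grid, while the ground truth
    keeps the exact event times.
    """
    if group not in config.n_subjects:
        raise ValueError(f"unknown group {group!r}")
    if condition not in config.templates:
        raise ValueError(f"no templates configured for condition {condition!r}")
    events_exact, truth = simulate_gait_events(
        config, group, condition, rng, subject=subject_id
    )
    n_samples = int(np.floor(truth.heel_strikes_exact[-1] * config.fs_emg)) + 1
    t = np.arange(n_samples) / config.fs_emg
    phi = cycle_phase(t, truth.heel_strikes_exact[:-1], truth.stride_durations)
    recordings: dict[str, EmgRecording] = {}
    for muscle in MUSCLES:
        template = config.templates[condition][muscle]
        amplitude = np.asarray(template(phi))
        raw = amplitude * rng.standard_normal(n_samples)
        recordings[muscle] = EmgRecording(
            samples=raw, fs=config.fs_emg, muscle=muscle, subject=subject_id,
            group=group, condition=condition, leg="right",
        )
    events_video = quantize_events(events_exact, config.fs_video)
    return recordings, events_video, truth


def simulate_phase_amplitudes(
    n_subjects: int,
    condition_gains: dict[str, float],
    rng: np.random.Generator,
    between_subject_sd: float = 0.3,
    within_subject_sd: float = 0.1,
) -> tuple[np.ndarray, list[str]]:
    """Per-subject phase-mean amplitudes drawn at the summary level.

    A lightweight arm of the generator for calibration studies that need
    thousands of replicates: instead of synthesizing waveforms it draws the
    per-subject, per-condition mean amplitude directly from the same
    multiplicative model the waveform generator induces —
    ``amp[s, c] = gain[c] * exp(b_s) * exp(e_sc)`` with lognormal
    between-subject scale ``b_s ~ N(0, between_sd)`` and within-subject
    condition-to-condition noise ``e_sc ~ N(0, within_sd)``.

    Returns an (n_subjects, n_conditions) array and the condition order.
    """
    conds = list(condition_gains)
    gains = np.array([condition_gains[c] for c in conds])
    b = rng.normal(0.0, between_subject_sd, (n_subjects, 1))
    e = rng.normal(0.0, within_subject_sd, (n_subjects, gains.size))
    return gains[None, :] * np.exp(b) * np.exp(e), conds


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig, out_dir) -> "object":
    """Simulate every subject x condition and write a study directory.

    Writes, per subject and condition, a wide delimited signal file with a
    JSON sidecar and an events JSON; plus a ground-truth table, a template
    table, a metadata index, and a run manifest. Fully deterministic under
    ``config.seed``. Returns the resulting :class:`~gaitsemg.pipeline.StudyLayout`.
    """
    from . import pipeline  # deferred: pipeline imports this module

    return pipeline.write_cohort(config, out_dir)
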