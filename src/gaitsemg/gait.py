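"""Stride construction from gait-event annotations.

A stride runs from one ipsilateral heel strike (HS) to the next; the
intervening toe off (TO) splits it into stance (HS to TO, foot on the
ground) and swing (TO to next HS). Events typically come from manual
annotation of 50 Hz video synchronized with the sEMG, so event times are
quantized to the video frame grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("gaitsemg")


class EventStructureError(ValueError):
    """Heel-strike / toe-off sequences do not strictly alternate."""


@dataclass
class GaitEventSeries:
    """Heel-strike and toe-off timestamps (seconds) for one leg.

    The merged sequence must strictly alternate HS, TO, HS, ... starting
    with a heel strike. ``source_rate`` is the sampling rate of the device
    that produced the annotations (50 Hz for video), or None for exact times.
    """

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    source_rate: float | None = None

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        self.validate()

    def validate(self) -> None:
        hs, to = self.heel_strikes, self.toe_offs
        for name, arr in (("heel_strikes", hs), ("toe_offs", to)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                i = int(np.argmin(np.diff(arr) > 0))
                raise EventStructureError(
                    f"{name} not strictly increasing at t={arr[i + 1]:.4f} s"
                )
        if to.size not in (hs.size, hs.size - 1):
            raise EventStructureError(
                f"cannot alternate {hs.size} heel strikes with {to.size} toe offs"
            )
        # strict HS < TO < next HS interleaving
        for i in range(to.size):
            if not hs[i] < to[i]:
                raise EventStructureError(
                    f"toe off at t={to[i]:.4f} s does not follow heel strike "
                    f"at t={hs[i]:.4f} s"
                )
            if i + 1 < hs.size and not to[i] < hs[i + 1]:
                raise EventStructureError(
                    f"heel strike at t={hs[i + 1]:.4f} s does not follow toe "
                    f"off at t={to[i]:.4f} s"
                )


@dataclass
class Stride:
    """One gait cycle: heel strike, toe off, next heel strike (seconds)."""

    hs: float
    to: float
    next_hs: float
    stance_s: float = field(init=False)
    swing_s: float = field(init=False)
    cycle_s: float = field(init=False)
    stance_pct: float = field(init=False)
    swing_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.hs < self.to < self.next_hs:
            raise EventStructureError(
                f"stride events must satisfy hs < to < next_hs, got "
                f"({self.hs}, {self.to}, {self.next_hs})"
            )
        self.cycle_s = self.next_hs - self.hs
        self.stance_s = self.to - self.hs
        self.swing_s = self.next_hs - self.to
        self.stance_pct = 100.0 * self.stance_s / self.cycle_s
        self.swing_pct = 100.0 - self.stance_pct

    @property
    def center(self) -> float:
        return 0.5 * (self.hs + self.next_hs)


def build_strides(events: GaitEventSeries) -> list[Stride]:
    """One stride per consecutive HS-TO-HS triple.

    Returns ``#HS - 1`` strides when the alternation invariant holds. Fewer
    than two heel strikes yields an empty list with a logged warning.
    """
    events.validate()
    hs = events.heel_strikes
    if hs.size < 2:
        logger.warning("fewer than 2 heel strikes: no strides built")
        return []
    if events.toe_offs.size < hs.size - 1:
        raise EventStructureError(
            f"missing toe off after heel strike at t={hs[-2]:.4f} s"
        )
    return [
        Stride(hs=hs[i], to=events.toe_offs[i], next_hs=hs[i + 1])
        for i in range(hs.size - 1)
    ]


def select_middle_strides(
    strides: list[Stride],
    k: int = 20,
    recording_span: tuple[float, float] | None = None,
) -> list[Stride]:
    """The k consecutive strides closest to the middle of the recording.

    Among all windows of k consecutive strides, picks the one whose span
    centre (midpoint between the window's first heel strike and last heel
    strike) is nearest the midpoint of ``recording_span``; an exact tie goes
    to the later window. Defaults ``recording_span`` to the full stride span.
    If fewer than k strides exist, all are returned with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not strides:
        raise ValueError("empty stride list")
    if len(strides) <= k:
        if len(strides) < k:
            logger.warning(
                "only %d strides available, %d requested: using all", len(strides), k
            )
        return list(strides)
    if recording_span is None:
        recording_span = (strides[0].hs, strides[-1].next_hs)
    target = 0.5 * (recording_span[0] + recording_span[1])
    centers = np.array(
        [0.5 * (strides[i].hs + strides[i + k - 1].next_hs) for i in range(len(strides) - k + 1)]
    )
    costs = np.abs(centers - target)
    # ties broken toward the later window
    best = costs.size - 1 - int(np.argmin(costs[::-1]))
    return list(strides[best : best + k])


def summarize_phase_distribution(strides: list[Stride]) -> tuple[float, float, float]:
    """(mean stance %, sample-SD stance %, mean swing %) over the strides.

    Uses the n-1 denominator for the SD; a single stride reports SD 0.
    """
    if not strides:
        raise ValueError("empty stride list")
    stance = np.array([s.stance_pct for s in strides])
    mean = float(np.mean(stance))
    sd = float(np.std(stance, ddof=1)) if stance.size > 1 else 0.0
    return mean, sd, 100.0 - mean
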