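"""Visual fall-stimulus protocol: rotation waveform and heelstrike-triggered scheduling.

The stimulus rotates the visual scene about the anterior-posterior axis to
induce the perception of a lateral fall.  The waveform is a constant angular
acceleration ramp, a constant hold at the peak angle, and a constant-velocity
return to neutral.  Stimuli are triggered on heelstrikes, with a randomized
washout of 10-13 steps (counting heelstrikes of both feet) after the scene
has returned to neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RotationProfileParams",
    "StimulusEvent",
    "BlockProtocol",
    "rotation_profile",
    "schedule_stimuli",
    "standing_trigger_threshold",
]


@dataclass(frozen=True)
class RotationProfileParams:
    """Parameters of the scene-rotation waveform.

    accel : angular acceleration of the ramp, deg/s^2
    accel_duration : duration of the acceleration ramp, s
    hold_duration : duration the peak angle is held, s
    reset_duration : duration of the constant-velocity return to neutral, s
    """

    accel: float = 60.0
    accel_duration: float = 0.6
    hold_duration: float = 2.0
    reset_duration: float = 1.0

    def __post_init__(self) -> None:
        for name in ("accel", "accel_duration", "hold_duration", "reset_duration"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def peak_angle(self) -> float:
        """Peak rotation angle in degrees: 1/2 * accel * accel_duration^2."""
        return 0.5 * self.accel * self.accel_duration**2

    @property
    def total_duration(self) -> float:
        """Time from trigger until the scene is back at neutral, s."""
        return self.accel_duration + self.hold_duration + self.reset_duration


@dataclass(frozen=True)
class StimulusEvent:
    """One visual fall stimulus.

    trigger_time : time of the triggering heelstrike, s
    trigger_foot : which foot's heelstrike triggered the stimulus
    direction : roll direction of the scene = direction of the perceived fall
    """

    trigger_time: float
    trigger_foot: str  # "left" | "right"
    direction: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.trigger_foot not in ("left", "right"):
            raise ValueError(f"trigger_foot must be 'left' or 'right', got {self.trigger_foot!r}")
        if self.direction not in ("left", "right"):
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")


def rotation_profile(t, params: RotationProfileParams | None = None):
    """Scene rotation angle (deg) at time ``t`` (s) after the trigger.

    Piecewise: quadratic ramp (constant acceleration) on
    ``[0, accel_duration]``, constant peak angle during the hold, linear
    (constant angular velocity) return to zero over ``reset_duration``,
    and zero afterwards.  Continuous everywhere.

    ``t`` may be a scalar or array; negative times are rejected.
    """
    if params is None:
        params = RotationProfileParams()
    scalar = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("rotation_profile requires t >= 0")

    t1 = params.accel_duration
    t2 = t1 + params.hold_duration
    t3 = t2 + params.reset_duration
    peak = params.peak_angle

    angle = np.zeros_like(t_arr)
    ramp = t_arr < t1
    angle[ramp] = 0.5 * params.accel * t_arr[ramp] ** 2
    hold = (t_arr >= t1) & (t_arr < t2)
    angle[hold] = peak
    reset = (t_arr >= t2) & (t_arr < t3)
    angle[reset] = peak * (1.0 - (t_arr[reset] - t2) / params.reset_duration)
    if scalar:
        return float(angle[0])
    return angle


def standing_trigger_threshold(standing_heel_height: float, margin_mm: float = 3.0) -> float:
    """Heelstrike trigger threshold: standing heel-marker height plus 3 mm.

    Online triggering detects downward crossings of this threshold by the
    vertical heel-marker position.
    """
    if not np.isfinite(standing_heel_height):
        raise ValueError("standing heel height must be finite")
    return float(standing_heel_height) + margin_mm


def _check_alternation(times: np.ndarray, feet: np.ndarray) -> None:
    if np.any(np.diff(times) <= 0):
        warnings.warn("heelstrike times are not strictly increasing", stacklevel=3)
    if len(feet) > 1 and np.any(feet[1:] == feet[:-1]):
        warnings.warn("heelstrikes do not alternate feet", stacklevel=3)


def schedule_stimuli(
    heelstrike_times,
    heelstrike_feet,
    seed: int | np.random.Generator = 0,
    min_gap: int = 10,
    max_gap: int = 13,
    params: RotationProfileParams | None = None,
) -> list[StimulusEvent]:
    """Place randomized fall stimuli on heelstrikes.

    After each stimulus completes (scene back at neutral,
    ``params.total_duration`` after the trigger), a washout of ``g`` steps
    is drawn uniformly from ``{min_gap, ..., max_gap}``; the stimulus
    triggers on the ``g``-th heelstrike (either foot) following reset
    completion.  The first stimulus uses the same draw counted from the
    start of the event stream.  Roll direction is drawn uniformly.
    Fully reproducible from ``seed``.
    """
    if params is None:
        params = RotationProfileParams()
    times = np.asarray(heelstrike_times, dtype=float)
    feet = np.asarray(heelstrike_feet, dtype=object)
    if times.size == 0:
        return []
    if times.shape != feet.shape:
        raise ValueError("heelstrike times and feet must have equal length")
    if min_gap < 1 or max_gap < min_gap:
        raise ValueError("need 1 <= min_gap <= max_gap")
    _check_alternation(times, feet)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    # index of the first heelstrike eligible for counting the washout
    start = 0
    while start < len(times):
        gap = int(rng.integers(min_gap, max_gap + 1))
        idx = start + gap - 1  # the gap-th eligible heelstrike
        if idx >= len(times):
            break
        direction = "left" if rng.random() < 0.5 else "right"
        events.append(
            StimulusEvent(
                trigger_time=float(times[idx]),
                trigger_foot=str(feet[idx]),
                direction=direction,
            )
        )
        reset_end = times[idx] + params.total_duration
        start = int(np.searchsorted(times, reset_end, side="right"))
    return events


def stimulus_log_frame(events: list[StimulusEvent], params: RotationProfileParams | None = None) -> pd.DataFrame:
    """Tidy stimulus log: time_s, trigger_foot, direction, peak_angle_deg."""
    if params is None:
        params = RotationProfileParams()
    return pd.DataFrame(
        {
            "time_s": [e.trigger_time for e in events],
            "trigger_foot": [e.trigger_foot for e in events],
            "direction": [e.direction for e in events],
            "peak_angle_deg": [params.peak_angle for e in events],
        }
    )


@dataclass(frozen=True)
class BlockProtocol:
    """One data-collection block: alternating metronome and stimulus phases.

    The default block is five 30 s metronome phases alternating with five
    120 s stimulus phases, always starting with a metronome phase; data are
    collected during the stimulus phases.
    """

    n_pairs: int = 5
    metronome_duration_s: float = 30.0
    stimulus_duration_s: float = 120.0
    metronome_bpm: float = 90.0

    @property
    def phases(self) -> list[tuple[str, float]]:
        out: list[tuple[str, float]] = []
        for _ in range(self.n_pairs):
            out.append(("metronome", self.metronome_duration_s))
            out.append(("stimulus", self.stimulus_duration_s))
        return out

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.phases)

    @property
    def total_duration_min(self) -> float:
        return self.total_duration_s / 60.0
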