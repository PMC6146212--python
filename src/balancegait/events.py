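"""Gait event detection from marker kinematics.

Heelstrikes are prominent minima of the vertical heel-marker trace;
pushoffs are the first prominent peak of the 2nd-metatarsal vertical
velocity after each ipsilateral heelstrike.  Prominence uses the standard
topographic definition (height of a peak above the higher of its two
flanking troughs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "GaitEvent",
    "detect_heelstrikes",
    "detect_pushoffs",
    "check_alternation",
    "review_events",
    "events_frame",
]

HEELSTRIKE_PROMINENCE_MM = 20.0
HEELSTRIKE_MIN_SPACING_S = 0.250
PUSHOFF_PROMINENCE_MM_S = 350.0


@dataclass(frozen=True)
class GaitEvent:
    time: float  # s
    foot: str  # "left" | "right"
    kind: str  # "heelstrike" | "pushoff"
    source: str = "auto"  # "auto" | "manual"


def detect_heelstrikes(
    heel_z,
    fs: float,
    foot: str,
    prominence_mm: float = HEELSTRIKE_PROMINENCE_MM,
    min_spacing_s: float = HEELSTRIKE_MIN_SPACING_S,
) -> list[GaitEvent]:
    """Heelstrikes of one foot: prominent minima of the vertical heel trace.

    All minima with prominence above ``prominence_mm`` are found first;
    the minimum spacing is then enforced greedily, keeping the more
    prominent of any conflicting pair.  Event time is the sample index of
    the extremum (no sub-sample interpolation).
    """
    z = np.asarray(heel_z, dtype=float)
    finite = np.isfinite(z)
    work = np.where(finite, z, np.nanmax(z[finite]) if finite.any() else 0.0)
    idx, props = find_peaks(-work, prominence=prominence_mm)
    if len(idx) == 0:
        return []
    # greedy non-maximum suppression by prominence
    order = np.argsort(props["prominences"])[::-1]
    min_dist = min_spacing_s * fs
    kept: list[int] = []
    for k in order:
        i = idx[k]
        if all(abs(i - j) >= min_dist for j in kept):
            kept.append(i)
    kept.sort()
    return [GaitEvent(time=i / fs, foot=foot, kind="heelstrike") for i in kept]


def detect_pushoffs(
    met2_z_velocity,
    fs: float,
    heelstrikes: list[GaitEvent],
    prominence_mm_s: float = PUSHOFF_PROMINENCE_MM_S,
) -> tuple[list[GaitEvent], list[GaitEvent]]:
    """Pushoffs of one foot: first prominent vertical-velocity peak of the
    2nd-metatarsal marker after each ipsilateral heelstrike.

    Returns ``(pushoffs, flagged)`` where ``flagged`` lists the
    heelstrikes for which no qualifying peak was found before the next
    ipsilateral heelstrike.
    """
    if not heelstrikes:
        return [], []
    v = np.asarray(met2_z_velocity, dtype=float)
    work = np.where(np.isfinite(v), v, np.nanmin(v[np.isfinite(v)]) if np.isfinite(v).any() else 0.0)
    idx, _ = find_peaks(work, prominence=prominence_mm_s)
    peak_times = idx / fs
    hs_times = np.array([e.time for e in heelstrikes])
    pushoffs: list[GaitEvent] = []
    flagged: list[GaitEvent] = []
    foot = heelstrikes[0].foot
    for k, hs in enumerate(hs_times):
        upper = hs_times[k + 1] if k + 1 < len(hs_times) else np.inf
        candidates = peak_times[(peak_times > hs) & (peak_times < upper)]
        if len(candidates) == 0:
            flagged.append(heelstrikes[k])
        else:
            pushoffs.append(GaitEvent(time=float(candidates[0]), foot=foot, kind="pushoff"))
    return pushoffs, flagged


def check_alternation(heelstrikes: list[GaitEvent]) -> list[int]:
    """Indices (into the time-sorted list) where feet fail to alternate.

    Violations are flagged, never silently fixed.
    """
    ordered = sorted(heelstrikes, key=lambda e: e.time)
    bad = [k for k in range(1, len(ordered)) if ordered[k].foot == ordered[k - 1].foot]
    if bad:
        warnings.warn(f"{len(bad)} heelstrike alternation violation(s)", stacklevel=2)
    return bad


def events_frame(events: list[GaitEvent]) -> pd.DataFrame:
    """Tidy events table: time_s, foot, kind, source."""
    return pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "foot": [e.foot for e in events],
            "kind": [e.kind for e in events],
            "source": [e.source for e in events],
        }
    ).sort_values("time_s", ignore_index=True)


def review_events(
    events: list[GaitEvent],
    overrides: pd.DataFrame | None,
    min_spacing_s: float = HEELSTRIKE_MIN_SPACING_S,
    time_tol: float = 1e-6,
) -> list[GaitEvent]:
    """Apply manual add/remove/move corrections from a reviewable table.

    ``overrides`` columns: ``action`` in {add, remove, move}, ``time_s``,
    ``foot``, ``kind``, and ``new_time_s`` for moves.  Edits that would
    break per-foot heelstrike ordering or the minimum spacing are rejected
    with an explanatory error; an empty table is the identity.
    """
    result = list(events)
    if overrides is None or len(overrides) == 0:
        return result

    def find(time: float, foot: str, kind: str) -> int:
        for i, e in enumerate(result):
            if e.foot == foot and e.kind == kind and abs(e.time - time) <= max(time_tol, 1e-9):
                return i
        raise ValueError(f"no {kind} event of {foot} foot at t={time}")

    for _, row in overrides.iterrows():
        action = row["action"]
        if action == "add":
            result.append(GaitEvent(float(row["time_s"]), row["foot"], row["kind"], source="manual"))
        elif action == "remove":
            del result[find(float(row["time_s"]), row["foot"], row["kind"])]
        elif action == "move":
            i = find(float(row["time_s"]), row["foot"], row["kind"])
            result[i] = GaitEvent(float(row["new_time_s"]), row["foot"], row["kind"], source="manual")
        else:
            raise ValueError(f"unknown override action {action!r}")
        _validate_spacing(result, min_spacing_s, context=f"{action} at t={row['time_s']}")
    return sorted(result, key=lambda e: e.time)


def _validate_spacing(events: list[GaitEvent], min_spacing_s: float, context: str) -> None:
    for foot in ("left", "right"):
        times = sorted(e.time for e in events if e.foot == foot and e.kind == "heelstrike")
        gaps = np.diff(times)
        if len(gaps) and gaps.min() < min_spacing_s:
            raise ValueError(
                f"override rejected ({context}): {foot} heelstrikes would be "
                f"{gaps.min() * 1000:.0f} ms apart, below the {min_spacing_s * 1000:.0f} ms minimum"
            )
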