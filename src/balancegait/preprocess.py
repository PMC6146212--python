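"""Signal conditioning: Butterworth filtering, marker gap filling, CoM, CoP, EMG.

Conventions: positions in mm, times in s, forces in N, moments in N*m.
Lateral axis is x (positive right), anterior y, vertical z.  All filtering
is zero-phase (forward-backward) so event timing is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

__all__ = [
    "ComState",
    "SegmentMassTable",
    "lowpass",
    "fill_gaps",
    "compute_com",
    "compute_cop",
    "emg_envelope",
    "emg_normalize",
]


@dataclass
class ComState:
    """Lateral center-of-mass state: position (mm), velocity (mm/s),
    acceleration (mm/s^2).  Velocity and acceleration are successive
    central-difference time derivatives of the position trace."""

    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray


@dataclass(frozen=True)
class SegmentMassTable:
    """Per-segment body mass fractions used for the CoM estimate.

    The default is a simplified 8-class table (arms and legs lumped per
    side); fractions must sum to 1.
    """

    fractions: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.fractions is None:
            object.__setattr__(self, "fractions", dict(DEFAULT_SEGMENT_FRACTIONS))
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions must sum to 1, got {total:.6f}")


# Simplified whole-body mass distribution (fraction of body mass per
# segment class; trunk/head values follow standard anthropometric tables,
# arms lumped into a single segment per side).
DEFAULT_SEGMENT_FRACTIONS: dict[str, float] = {
    "pelvis": 0.142,
    "torso": 0.355,
    "head": 0.081,
    "thigh_left": 0.100,
    "thigh_right": 0.100,
    "shank_left": 0.0465,
    "shank_right": 0.0465,
    "foot_left": 0.0145,
    "foot_right": 0.0145,
    "arm_left": 0.050,
    "arm_right": 0.050,
}


def _filtfilt_nan_aware(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    """filtfilt over each contiguous finite run; NaN runs are left in place."""
    y = np.array(x, dtype=float, copy=True)
    finite = np.isfinite(y)
    if finite.all():
        return filtfilt(b, a, y)
    # boundaries of finite runs
    idx = np.flatnonzero(np.diff(np.concatenate(([0], finite.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        seg = y[start:stop]
        default_padlen = 3 * (max(len(a), len(b)) - 1)
        padlen = min(default_padlen, len(seg) - 1)
        if padlen < 1:
            continue  # too short to filter; keep raw
        y[start:stop] = filtfilt(b, a, seg, padlen=padlen)
    return y


def lowpass(signal, fs: float, fc: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (DC gain 1).

    Applied forward-backward, so the effective attenuation is the squared
    magnitude response of the designed filter.  2-D input is filtered
    column-wise.  NaN-bearing channels are filtered piecewise over their
    finite runs.
    """
    if not 0 < fc < fs / 2:
        raise ValueError(f"cutoff must satisfy 0 < fc < fs/2 (fc={fc}, fs={fs})")
    b, a = butter(order, fc / (fs / 2.0), btype="low")
    x = np.asarray(signal, dtype=float)
    if x.ndim == 1:
        return _filtfilt_nan_aware(b, a, x)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        out[:, j] = _filtfilt_nan_aware(b, a, x[:, j])
    return out


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def fill_gaps(
    traj,
    fs: float,
    max_gap_ms: float = 100.0,
    flank: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short occlusion gaps (NaN runs) with local cubic splines.

    Runs of NaN no longer than ``max_gap_ms`` with finite samples on both
    sides are replaced by a cubic spline fitted to up to ``flank`` finite
    samples on each side.  Longer runs, and runs touching the trace ends,
    are left as NaN and reported in the exclusion mask.

    Returns ``(filled, excluded_mask)``; the mask is True where samples
    remain unusable.  2-D input is processed column-wise.
    """
    x = np.array(traj, dtype=float, copy=True)
    if x.ndim == 2:
        masks = []
        for j in range(x.shape[1]):
            x[:, j], m = fill_gaps(x[:, j], fs, max_gap_ms, flank)
            masks.append(m)
        return x, np.column_stack(masks)

    nan_mask = ~np.isfinite(x)
    excluded = np.zeros_like(nan_mask)
    if not nan_mask.any():
        return x, excluded
    if nan_mask.all():
        warnings.warn("channel is entirely occluded; excluding it", stacklevel=2)
        return x, np.ones_like(nan_mask)

    max_len = int(round(max_gap_ms * fs / 1000.0))
    for start, stop in _nan_runs(nan_mask):
        run_len = stop - start
        at_edge = start == 0 or stop == len(x)
        if run_len > max_len or at_edge:
            excluded[start:stop] = True
            continue
        left = np.arange(max(0, start - flank), start)
        right = np.arange(stop, min(len(x), stop + flank))
        support = np.concatenate([left, right])
        support = support[np.isfinite(x[support])]
        if (support < start).sum() < 2 or (support >= stop).sum() < 2:
            excluded[start:stop] = True
            continue
        spline = CubicSpline(support, x[support])
        x[start:stop] = spline(np.arange(start, stop))
    return x, excluded


def compute_com(
    segment_positions,
    table: SegmentMassTable | None = None,
    fs: float = 250.0,
) -> ComState:
    """Lateral whole-body CoM state from per-segment CoM positions.

    ``segment_positions`` maps segment name -> lateral position trace (mm).
    The CoM is the mass-fraction-weighted mean; velocity and acceleration
    are successive central differences (``np.gradient``) at ``fs``.
    """
    if table is None:
        table = SegmentMassTable()
    if hasattr(segment_positions, "columns"):  # DataFrame
        segment_positions = {c: segment_positions[c].to_numpy() for c in segment_positions.columns}
    missing = [name for name in table.fractions if name not in segment_positions]
    if missing:
        raise KeyError(f"missing segment position(s): {', '.join(sorted(missing))}")
    pos = None
    for name, frac in table.fractions.items():
        contrib = frac * np.asarray(segment_positions[name], dtype=float)
        pos = contrib if pos is None else pos + contrib
    dt = 1.0 / fs
    vel = np.gradient(pos, dt)
    acc = np.gradient(vel, dt)
    return ComState(position=pos, velocity=vel, acceleration=acc)


def compute_cop(
    fz,
    mx,
    plate_origins_mm,
    fz_threshold: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-body lateral CoP (mm) from per-plate vertical forces and moments.

    ``fz`` and ``mx`` are (time x plates) arrays: vertical force (N) and
    the moment component (N*m) that maps to the lateral CoP under this
    package's axis convention, ``cop_x = origin_x + 1000 * mx / fz``.
    Plates with vertical load below ``fz_threshold`` are treated as
    unloaded; the whole-body CoP is the vertical-force-weighted mean over
    loaded plates in the common (treadmill) frame.

    Returns ``(cop_mm, valid_mask)``; samples with no loaded plate are NaN
    and flagged invalid.
    """
    fz = np.asarray(fz, dtype=float)
    mx = np.asarray(mx, dtype=float)
    if fz.ndim == 1:  # single plate given as (time,)
        fz = fz[:, None]
        mx = mx[:, None]
    if fz.shape != mx.shape:
        raise ValueError("fz and mx must have the same shape")
    origins = np.asarray(plate_origins_mm, dtype=float).reshape(1, -1)
    if origins.shape[1] != fz.shape[1]:
        raise ValueError("one plate origin per plate is required")

    loaded = fz > fz_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        plate_cop = origins + 1000.0 * mx / fz
    weights = np.where(loaded, fz, 0.0)
    total = weights.sum(axis=1)
    valid = total > 0
    cop = np.full(fz.shape[0], np.nan)
    cop[valid] = (weights * np.where(loaded, plate_cop, 0.0)).sum(axis=1)[valid] / total[valid]
    return cop, valid


def emg_envelope(raw, fs: float, fc: float = 6.0, order: int = 4) -> np.ndarray:
    """EMG linear envelope: full-wave rectification then zero-phase low-pass."""
    return lowpass(np.abs(np.asarray(raw, dtype=float)), fs, fc, order)


def emg_normalize(envelope, control_mask) -> np.ndarray:
    """Normalize an EMG envelope so the control-stride grand mean is 100 %.

    ``control_mask`` selects the samples belonging to control strides.
    """
    env = np.asarray(envelope, dtype=float)
    mask = np.asarray(control_mask, dtype=bool)
    if not mask.any():
        raise ValueError("control stride set is empty")
    ref = np.nanmean(env[mask])
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("control-stride mean activation is zero or undefined")
    return env / ref * 100.0
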