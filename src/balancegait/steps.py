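"""Step segmentation, time normalization, perturbation-locked responses,
outcome variables, the CoM-state foot-placement model, and onset estimation.

A *step* runs from one heelstrike to the contralateral heelstrike.  For
each fall stimulus the four steps following the triggering heelstrike
(indices +1..+4) and the two preceding it (-2, -1; the controls) are
analyzed.  All trajectories are time-normalized to 100 points.

Channel naming inside a StepRecord is role-based: ``stance_*`` refers to
the leg on the ground when the step starts (for step +1 this is the
triggering leg), ``swing_*`` to the leg that lands at the end of the
step.  Lateral (spatial) channels are mirrored for left-foot-triggered
stimuli so that positive always means toward the triggering leg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import t as t_dist

from .events import GaitEvent
from .stimulus import StimulusEvent

__all__ = [
    "StepRecord",
    "FootPlacementModel",
    "OutcomeRow",
    "OnsetEstimate",
    "SPATIAL_CHANNELS",
    "segment_steps",
    "segment_and_select",
    "normalize_time",
    "classify_and_mirror",
    "mirror_record",
    "baseline_subtract",
    "fit_foot_placement_model",
    "stimulus_induced_fp_change",
    "compute_outcomes",
    "estimate_onset",
    "pointwise_ci",
    "outcomes_frame",
]

N_POINTS = 100
MIN_STEP_DURATION_S = 0.050
MIDSTANCE_FRACTION = 0.5  # operational definition of midstance (configurable)

# lateral/spatial channels: sign flips under left-right mirroring
SPATIAL_CHANNELS = frozenset(
    {
        "com_pos",
        "com_vel",
        "cop",
        "cop_rel",
        "rel_heel_x",
        "stance_heel_x",
        "swing_heel_x",
    }
)


@dataclass
class StepRecord:
    """One step with 100-point normalized trajectories and labels."""

    subject: str
    stance_foot: str
    swing_foot: str
    t_start: float
    t_end: float
    duration: float
    traj: dict[str, np.ndarray]
    pushoff_frac: float | None = None  # swing-leg pushoff, fraction of step time
    step_index: int | None = None  # -2..-1, 1..4 relative to the stimulus
    stimulus_id: int | None = None
    condition: str = "unlabeled"  # control | toward | away | unlabeled
    trigger_foot: str | None = None
    direction: str | None = None
    mirrored: bool = False
    is_response: bool = False  # True once the control baseline is subtracted
    step_length: float | None = None  # mm, anterior heel-to-heel at landing
    excluded: bool = False
    exclusion_reason: str | None = None

    def copy(self) -> "StepRecord":
        return replace(self, traj={k: v.copy() for k, v in self.traj.items()})


@dataclass(frozen=True)
class FootPlacementModel:
    """Per-subject linear model of foot-placement change on the CoM state
    (lateral position and velocity) at midstance, fitted on control steps."""

    subject: str
    intercept: float
    coef_pos: float  # mm per mm
    coef_vel: float  # mm per mm/s
    n_steps: int
    residual_sd: float

    def predict(self, com_pos_mid, com_vel_mid):
        return self.intercept + self.coef_pos * np.asarray(com_pos_mid) + self.coef_vel * np.asarray(com_vel_mid)


@dataclass
class OutcomeRow:
    """The seven outcome variables of one first-post-stimulus step,
    sign-adjusted so positive means a response in the expected direction
    (spatial variables inverted for *away*, body-relative for *toward*)."""

    subject: str
    trigger_foot: str
    direction: str  # toward | away
    foot_placement_change: float | None = None  # mm
    stimulus_induced_fp_change: float | None = None  # mm
    hip_abduction_change: float | None = None  # deg
    integrated_gluteus_medius_emg_change: float | None = None  # % s
    integrated_relative_cop_change: float | None = None  # mm s
    ankle_eversion_change: float | None = None  # deg
    integrated_peroneus_longus_emg_change: float | None = None  # % s


@dataclass
class OnsetEstimate:
    """Tangent-extrapolation onset of a pooled response."""

    variable: str
    condition: str
    onset_ms: float | None  # None when no CI-exclusion region exists
    slope: float | None = None  # response units per s at the anchor
    anchor_ms: float | None = None
    anchor_value: float | None = None
    region_ms: tuple[float, float] | None = None  # CI-exclusion window
    n_pooled: int = 0


def normalize_time(t, y, n_points: int = N_POINTS) -> np.ndarray:
    """Resample one step's samples onto ``n_points`` evenly spaced time
    points including both endpoints (endpoint values preserved)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("a step needs at least 2 samples to normalize")
    if t[-1] - t[0] < MIN_STEP_DURATION_S:
        raise ValueError(f"degenerate step (< {MIN_STEP_DURATION_S * 1000:.0f} ms)")
    grid = np.linspace(t[0], t[-1], n_points)
    return np.interp(grid, t, y)


def segment_steps(heelstrikes: list[GaitEvent]) -> pd.DataFrame:
    """All steps (heelstrike to contralateral heelstrike) in a trial."""
    ordered = sorted((e for e in heelstrikes if e.kind == "heelstrike"), key=lambda e: e.time)
    rows = []
    for a, b in zip(ordered[:-1], ordered[1:]):
        if a.foot == b.foot:
            continue  # alternation violation; flagged upstream
        rows.append(
            {
                "t_start": a.time,
                "t_end": b.time,
                "stance_foot": a.foot,
                "swing_foot": b.foot,
            }
        )
    return pd.DataFrame(rows)


def _label_steps(step_table: pd.DataFrame, stimuli: list[StimulusEvent],
                 n_pre: int = 2, n_post: int = 4, tol: float = 0.02) -> pd.DataFrame:
    """Attach stimulus-relative step indices (-2..-1, +1..+4)."""
    table = step_table.copy()
    table["step_index"] = pd.array([None] * len(table), dtype="Int64")
    table["stimulus_id"] = pd.array([None] * len(table), dtype="Int64")
    starts = table["t_start"].to_numpy()
    for sid, ev in enumerate(stimuli):
        hits = np.flatnonzero(np.abs(starts - ev.trigger_time) < tol)
        if len(hits) == 0:
            warnings.warn(f"stimulus at t={ev.trigger_time:.3f} s has no matching heelstrike step")
            continue
        k = int(hits[0])
        for offset in range(-n_pre, n_post + 1):
            if offset == 0:
                idx = k  # step +1 starts at the triggering heelstrike
                label = 1
            elif offset > 0:
                idx = k + offset
                label = offset + 1
            else:
                idx = k + offset
                label = offset
            if label > n_post or not 0 <= idx < len(table):
                continue
            table.loc[table.index[idx], "step_index"] = label
            table.loc[table.index[idx], "stimulus_id"] = sid
    return table


def segment_and_select(
    heelstrikes: list[GaitEvent],
    pushoffs: list[GaitEvent],
    stimuli: list[StimulusEvent],
    channels: dict[str, tuple[np.ndarray, np.ndarray]],
    subject: str = "S01",
    excluded_times: list[tuple[float, float]] | None = None,
    n_pre: int = 2,
    n_post: int = 4,
) -> list[StepRecord]:
    """Build StepRecords for the six analysis steps around each stimulus.

    ``channels`` maps channel name -> (time vector, signal); ``stance_*``
    / ``swing_*`` channel templates carry a ``{side}`` placeholder, e.g.
    ``{"stance_heel_x": (t, {"left": xl, "right": xr}), "com_pos": (t, x)}``
    is expressed by passing per-side dicts as the signal.  Steps touching
    an excluded (occluded) interval, or degenerate steps, are kept but
    flagged with an exclusion reason.
    """
    table = _label_steps(segment_steps(heelstrikes), stimuli, n_pre, n_post)
    po_by_foot = {
        "left": np.array(sorted(e.time for e in pushoffs if e.foot == "left")),
        "right": np.array(sorted(e.time for e in pushoffs if e.foot == "right")),
    }
    excluded_times = excluded_times or []
    records: list[StepRecord] = []
    for _, row in table.iterrows():
        if pd.isna(row["step_index"]) and stimuli:
            continue  # only the six steps around each stimulus are analyzed
        t0, t1 = float(row["t_start"]), float(row["t_end"])
        sid = None if pd.isna(row["stimulus_id"]) else int(row["stimulus_id"])
        idx = None if pd.isna(row["step_index"]) else int(row["step_index"])
        stance, swing = row["stance_foot"], row["swing_foot"]
        reason = None
        if t1 - t0 < MIN_STEP_DURATION_S:
            reason = "degenerate step"
        for a, b in excluded_times:
            if a < t1 and b > t0:
                reason = "overlaps occluded samples"
                break
        traj: dict[str, np.ndarray] = {}
        if reason is None:
            try:
                for name, (t, sig) in channels.items():
                    if isinstance(sig, dict):  # per-side channel
                        side = stance if name.startswith("stance_") else swing
                        y = sig[side]
                    else:
                        y = sig
                    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
                    seg_t, seg_y = t[sel], y[sel]
                    if not np.all(np.isfinite(seg_y)):
                        raise ValueError(f"missing data in channel {name}")
                    traj[name] = normalize_time(seg_t, seg_y)
            except ValueError as err:
                reason = str(err)
                traj = {}
        po_frac = None
        po = po_by_foot.get(swing, np.array([]))
        inside = po[(po > t0) & (po < t1)]
        if len(inside):
            po_frac = float((inside[0] - t0) / (t1 - t0))
        elif reason is None:
            reason = "no swing-leg pushoff inside step"
        step_length = None
        if "stance_heel_y" in traj and "swing_heel_y" in traj:
            step_length = float(traj["swing_heel_y"][-1] - traj["stance_heel_y"][-1])
        records.append(
            StepRecord(
                subject=subject,
                stance_foot=stance,
                swing_foot=swing,
                t_start=t0,
                t_end=t1,
                duration=t1 - t0,
                traj=traj,
                pushoff_frac=po_frac,
                step_index=idx,
                stimulus_id=sid,
                condition="control" if idx in (-2, -1) else ("unlabeled" if idx is None else "stimulus"),
                excluded=reason is not None,
                exclusion_reason=reason,
                step_length=step_length,
            )
        )
    return records


def classify_and_mirror(record: StepRecord, stimulus: StimulusEvent) -> StepRecord:
    """Label a step toward/away and mirror left-triggered spatial signals.

    By body symmetry, a perceived fall toward the side of the triggering
    foot is *toward*, otherwise *away*.  For left-foot triggers all
    lateral spatial channels are negated, so that positive always means
    toward the triggering leg.  Control steps keep their condition label
    but are mirrored with their stimulus.
    """
    out = record.copy()
    out.trigger_foot = stimulus.trigger_foot
    out.direction = "toward" if stimulus.direction == stimulus.trigger_foot else "away"
    if out.condition != "control":
        out.condition = out.direction
    if stimulus.trigger_foot == "left":
        out = mirror_record(out)
    return out


def mirror_record(record: StepRecord) -> StepRecord:
    """Negate all lateral spatial channels (an involution)."""
    out = record.copy()
    for name in out.traj:
        if name in SPATIAL_CHANNELS:
            out.traj[name] = -out.traj[name]
    out.mirrored = not record.mirrored
    return out


def baseline_subtract(
    stimulus_steps: list[StepRecord],
    control_steps: list[StepRecord],
) -> list[StepRecord]:
    """Subtract the mean control trajectory (matched stance foot) pointwise.

    Returns response records (``is_response=True``).  Raises if a stance
    side has no usable control steps.
    """
    baselines: dict[str, dict[str, np.ndarray]] = {}
    for foot in ("left", "right"):
        group = [s for s in control_steps if s.stance_foot == foot and not s.excluded]
        if not group:
            continue
        channels = set.intersection(*(set(s.traj) for s in group))
        baselines[foot] = {
            name: np.mean([s.traj[name] for s in group], axis=0) for name in channels
        }
    responses = []
    for step in stimulus_steps:
        if step.excluded:
            responses.append(step.copy())
            continue
        if step.stance_foot not in baselines:
            raise ValueError(f"no control steps with stance foot {step.stance_foot!r}")
        base = baselines[step.stance_foot]
        out = step.copy()
        out.traj = {name: step.traj[name] - base[name] for name in base if name in step.traj}
        out.is_response = True
        responses.append(out)
    return responses


def _midstance_value(y: np.ndarray, fraction: float = MIDSTANCE_FRACTION) -> float:
    pos = fraction * (len(y) - 1)
    return float(np.interp(pos, np.arange(len(y)), y))


def fit_foot_placement_model(
    control_responses: list[StepRecord],
    min_steps: int = 10,
    midstance_fraction: float = MIDSTANCE_FRACTION,
) -> FootPlacementModel:
    """OLS of foot-placement change on the CoM lateral position and
    velocity at midstance, using control-step responses only.

    The foot-placement change of a step is its relative-heel response at
    the step-ending heelstrike; the CoM regressors are the response
    values at the midstance point.
    """
    usable = [s for s in control_responses if not s.excluded and s.is_response]
    if len(usable) < min_steps:
        raise ValueError(f"need at least {min_steps} control steps, got {len(usable)}")
    y = np.array([s.traj["rel_heel_x"][-1] for s in usable])
    pos = np.array([_midstance_value(s.traj["com_pos"], midstance_fraction) for s in usable])
    vel = np.array([_midstance_value(s.traj["com_vel"], midstance_fraction) for s in usable])
    X = np.column_stack([np.ones_like(pos), pos, vel])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: CoM state has no variation across control steps")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - 3, 1)
    return FootPlacementModel(
        subject=usable[0].subject,
        intercept=float(beta[0]),
        coef_pos=float(beta[1]),
        coef_vel=float(beta[2]),
        n_steps=len(usable),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


def stimulus_induced_fp_change(
    step_response: StepRecord,
    model: FootPlacementModel,
    midstance_fraction: float = MIDSTANCE_FRACTION,
) -> float:
    """Observed foot-placement change minus the component predicted from
    the CoM state at midstance: the part attributable to the stimulus."""
    observed = float(step_response.traj["rel_heel_x"][-1])
    pos = _midstance_value(step_response.traj["com_pos"], midstance_fraction)
    vel = _midstance_value(step_response.traj["com_vel"], midstance_fraction)
    return observed - float(model.predict(pos, vel))


def _integrate_window(resp: np.ndarray, duration: float, start_frac: float) -> float:
    """Time integral (response units * s) from ``start_frac`` of the step
    to its end, on the real-time scale."""
    n = len(resp)
    dt = duration / (n - 1)
    i0 = int(np.ceil(start_frac * (n - 1)))
    return float(np.trapezoid(resp[i0:], dx=dt))


def compute_outcomes(
    step_response: StepRecord,
    model: FootPlacementModel | None,
) -> OutcomeRow:
    """The seven outcome variables for one first-post-stimulus step.

    End-of-step angle changes for hip abduction and ankle eversion;
    real-time integrals over the first post-stimulus swing phase (from
    the swing-leg pushoff to the step-ending heelstrike) for the EMG and
    relative-CoP variables.  Signs are adjusted so that positive means a
    response in the fall direction: spatial variables are inverted for
    *away* stimuli, body-relative ones for *toward*.
    """
    step = step_response
    if step.step_index != 1:
        raise ValueError("outcomes are defined for step +1 only")
    if step.excluded:
        raise ValueError(f"step is excluded: {step.exclusion_reason}")
    if not step.is_response:
        raise ValueError("outcomes require baseline-subtracted responses")
    if step.direction not in ("toward", "away"):
        raise ValueError("step must be classified toward/away first")
    spatial_sign = 1.0 if step.direction == "toward" else -1.0
    body_sign = -spatial_sign
    po_frac = step.pushoff_frac if step.pushoff_frac is not None else 0.0

    row = OutcomeRow(subject=step.subject, trigger_foot=step.trigger_foot, direction=step.direction)
    traj = step.traj
    if "rel_heel_x" in traj:
        fp_change = float(traj["rel_heel_x"][-1])
        row.foot_placement_change = spatial_sign * fp_change
        if model is not None:
            row.stimulus_induced_fp_change = spatial_sign * stimulus_induced_fp_change(step, model)
    if "swing_hip_abduction" in traj:
        row.hip_abduction_change = body_sign * float(traj["swing_hip_abduction"][-1])
    if "stance_ankle_eversion" in traj:
        row.ankle_eversion_change = body_sign * float(traj["stance_ankle_eversion"][-1])
    if "cop_rel" in traj:
        row.integrated_relative_cop_change = spatial_sign * _integrate_window(
            traj["cop_rel"], step.duration, po_frac
        )
    if "swing_emg_gluteus_medius" in traj:
        row.integrated_gluteus_medius_emg_change = body_sign * _integrate_window(
            traj["swing_emg_gluteus_medius"], step.duration, po_frac
        )
    if "stance_emg_peroneus_longus" in traj:
        row.integrated_peroneus_longus_emg_change = body_sign * _integrate_window(
            traj["stance_emg_peroneus_longus"], step.duration, po_frac
        )
    return row


def outcomes_frame(rows: list[OutcomeRow]) -> pd.DataFrame:
    """Tidy outcomes table, one row per first-post-stimulus step."""
    return pd.DataFrame([vars(r) for r in rows])


def pointwise_ci(trajectories, alpha: float = 0.05):
    """Pointwise mean and 95% CI band assuming independent normal data at
    each normalized time point: mean +- t(1-alpha/2, n-1) * SE."""
    Y = np.asarray(trajectories, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("need at least 2 trajectories for a CI band")
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    se = Y.std(axis=0, ddof=1) / np.sqrt(n)
    q = t_dist.ppf(1.0 - alpha / 2.0, n - 1)
    return mean, mean - q * se, mean + q * se


def _exclusion_regions(lower: np.ndarray, upper: np.ndarray) -> list[tuple[int, int]]:
    mask = (lower > 0) | (upper < 0)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def estimate_onset(
    responses,
    duration_s: float,
    variable: str = "",
    condition: str = "",
    alpha: float = 0.05,
    min_region_ms: float = 50.0,
) -> OnsetEstimate:
    """Tangent-extrapolation onset of a pooled response.

    1. Pointwise (1-alpha) CI of the mean over the pooled repeats.
    2. Range of interest: the longest contiguous region (at least
       ``min_region_ms`` long) where the CI excludes zero.
    3. First local maximum of the mean's rate of change (central
       differences, no extra smoothing) inside that region, rectified by
       the response direction.
    4. The tangent line at that point; its zero crossing is the onset,
       in ms after the stimulus trigger (= step start).

    Returns an estimate with ``onset_ms=None`` when no exclusion region
    exists.
    """
    Y = np.asarray(responses, dtype=float)
    mean, lower, upper = pointwise_ci(Y, alpha=alpha)
    n = Y.shape[1]
    dt = duration_s / (n - 1)
    regions = _exclusion_regions(lower, upper)
    min_len = max(int(round(min_region_ms / 1000.0 / dt)), 1)
    regions = [r for r in regions if r[1] - r[0] >= min_len]
    if not regions:
        return OnsetEstimate(variable=variable, condition=condition, onset_ms=None, n_pooled=Y.shape[0])
    start, stop = max(regions, key=lambda r: r[1] - r[0])

    sign = 1.0 if mean[start:stop].mean() >= 0 else -1.0
    rate = np.gradient(sign * mean, dt)
    seg = rate[start:stop]
    # first local maximum of the rate of change inside the region; minor
    # tail wiggles are ignored by requiring at least half the region's
    # peak rate, and a region that starts past the rate peak (derivative
    # already falling) anchors at its largest-rate sample
    peaks, _ = find_peaks(seg, height=0.5 * float(np.max(seg)))
    anchor = start + (int(peaks[0]) if len(peaks) else int(np.argmax(seg)))
    slope = rate[anchor]
    value_rect = sign * mean[anchor]  # rectified response at the anchor
    t_anchor = anchor * dt
    if slope <= 0:
        onset = t_anchor
    else:
        onset = t_anchor - value_rect / slope
    onset = float(np.clip(onset, 0.0, duration_s))
    return OnsetEstimate(
        variable=variable,
        condition=condition,
        onset_ms=onset * 1000.0,
        slope=float(sign * slope),
        anchor_ms=t_anchor * 1000.0,
        anchor_value=float(mean[anchor]),
        region_ms=(start * dt * 1000.0, (stop - 1) * dt * 1000.0),
        n_pooled=Y.shape[0],
    )
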