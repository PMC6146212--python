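"""End-to-end analysis of one walking trial.

Chains the processing stages: filtering and gap handling, gait-event
detection, CoM/CoP/EMG conditioning, step segmentation around each fall
stimulus, baseline subtraction, mirroring, the foot-placement model, the
seven outcome variables, and response-onset estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import preprocess as pp
from . import steps as st
from .io import TrialBundle
from .stimulus import StimulusEvent

__all__ = [
    "AnalysisOptions",
    "TrialAnalysis",
    "analyze_trial",
    "pooled_onsets",
    "recovery_study",
]

# channels whose occlusions invalidate a step
_CRITICAL_MARKERS = ("heel_l_x", "heel_l_z", "heel_r_x", "heel_r_z", "met2_l_z", "met2_r_z")

_EMG_CHANNELS = {
    "swing_emg_gluteus_medius": "gluteus_medius",
    "stance_emg_peroneus_longus": "peroneus_longus",
    "stance_emg_gastrocnemius_medialis": "gastrocnemius_medialis",
}

_ANGLE_CHANNELS = {
    "stance_ankle_eversion": "ankle_eversion",
    "stance_ankle_plantarflexion": "ankle_plantarflexion",
    "swing_hip_abduction": "hip_abduction",
    "swing_hip_rotation": "hip_rotation",
    "stance_knee_rotation": "knee_rotation",
}


@dataclass(frozen=True)
class AnalysisOptions:
    """Filter cutoffs and analysis parameters (all overridable)."""

    fc_kinematics_hz: float = 10.0
    fc_forces_hz: float = 50.0
    fc_emg_hz: float = 6.0
    max_gap_ms: float = 100.0
    midstance_fraction: float = st.MIDSTANCE_FRACTION
    min_control_steps: int = 10
    fz_threshold_n: float = 20.0


@dataclass
class TrialAnalysis:
    """Everything the per-trial pipeline produced."""

    subject: str
    heelstrikes: list
    pushoffs: list
    stimuli: list[StimulusEvent]
    records: list[st.StepRecord]  # raw (not baseline-subtracted)
    responses: list[st.StepRecord]  # baseline-subtracted, mirrored, labeled
    control_responses: list[st.StepRecord]
    fp_model: st.FootPlacementModel | None
    outcomes: pd.DataFrame
    n_excluded: int = 0
    exclusion_reasons: dict = field(default_factory=dict)


def _mask_to_intervals(mask: np.ndarray, t: np.ndarray) -> list[tuple[float, float]]:
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(t[a], t[min(b, len(t) - 1)]) for a, b in zip(idx[::2], idx[1::2])]


def analyze_trial(bundle: TrialBundle, options: AnalysisOptions | None = None) -> TrialAnalysis:
    """Run the full analysis chain on one trial bundle."""
    opt = options or AnalysisOptions()
    fs_m = bundle.marker_fs
    fs_a = bundle.analog_fs
    t_m = bundle.markers["time_s"].to_numpy()
    t_a = bundle.forces["time_s"].to_numpy()
    subject = str(bundle.meta.get("subject", "S01"))

    # --- markers: gap filling then 10 Hz zero-phase low-pass --------------
    filled: dict[str, np.ndarray] = {}
    excluded_times: list[tuple[float, float]] = []
    for col in bundle.markers.columns:
        if col == "time_s":
            continue
        y, excl = pp.fill_gaps(bundle.markers[col].to_numpy(), fs_m, opt.max_gap_ms)
        filled[col] = pp.lowpass(y, fs_m, opt.fc_kinematics_hz)
        if excl.any():
            excluded_times.extend(_mask_to_intervals(excl, t_m))

    # --- gait events ------------------------------------------------------
    heelstrikes: list[ev.GaitEvent] = []
    pushoffs: list[ev.GaitEvent] = []
    for foot, pfx in (("left", "l"), ("right", "r")):
        hs = ev.detect_heelstrikes(filled[f"heel_{pfx}_z"], fs_m, foot)
        vel = np.gradient(filled[f"met2_{pfx}_z"], 1.0 / fs_m)
        po, _flagged = ev.detect_pushoffs(vel, fs_m, hs)
        heelstrikes.extend(hs)
        pushoffs.extend(po)
    heelstrikes.sort(key=lambda e: e.time)
    ev.check_alternation(heelstrikes)

    # --- CoM --------------------------------------------------------------
    segment_cols = {
        name: filled[f"{name}_x"]
        for name in pp.DEFAULT_SEGMENT_FRACTIONS
        if f"{name}_x" in filled
    }
    com = pp.compute_com(segment_cols, fs=fs_m)

    # --- CoP --------------------------------------------------------------
    origins = bundle.meta.get("plate_origins_mm", {"left": 0.0, "right": 0.0})
    fz = np.column_stack(
        [
            pp.lowpass(bundle.forces["fz_l"].to_numpy(), fs_a, opt.fc_forces_hz),
            pp.lowpass(bundle.forces["fz_r"].to_numpy(), fs_a, opt.fc_forces_hz),
        ]
    )
    mx = np.column_stack(
        [
            pp.lowpass(bundle.forces["mx_l"].to_numpy(), fs_a, opt.fc_forces_hz),
            pp.lowpass(bundle.forces["mx_r"].to_numpy(), fs_a, opt.fc_forces_hz),
        ]
    )
    cop_a, _valid = pp.compute_cop(
        fz, mx, [origins["left"], origins["right"]], fz_threshold=opt.fz_threshold_n
    )
    cop = np.interp(t_m, t_a, cop_a)
    cop_rel = cop - com.position

    # --- stimuli and the step layout (needed for the EMG reference) -------
    stimuli = [
        StimulusEvent(float(r["time_s"]), str(r["trigger_foot"]), str(r["direction"]))
        for _, r in bundle.stimulus_log.iterrows()
    ]
    step_table = st._label_steps(st.segment_steps(heelstrikes), stimuli)
    if stimuli:
        ctrl = step_table[step_table["step_index"].isin([-2, -1])]
    else:
        ctrl = step_table
    control_mask = np.zeros(len(t_a), dtype=bool)
    for _, r in ctrl.iterrows():
        control_mask |= (t_a >= r["t_start"]) & (t_a <= r["t_end"])
    if not control_mask.any():
        control_mask[:] = True

    # --- EMG envelopes, normalized to the control-stride mean -------------
    emg_norm: dict[str, dict[str, np.ndarray]] = {}
    for muscle in {m for m in _EMG_CHANNELS.values()}:
        per_side = {}
        for foot, pfx in (("left", "l"), ("right", "r")):
            col = f"{muscle}_{pfx}"
            if col not in bundle.emg.columns:
                continue
            env = pp.emg_envelope(bundle.emg[col].to_numpy(), fs_a, opt.fc_emg_hz)
            env = pp.emg_normalize(env, control_mask)
            per_side[foot] = np.interp(t_m, t_a, env)
        if len(per_side) == 2:
            emg_norm[muscle] = per_side

    # --- channel map for step extraction ----------------------------------
    heel_x = {"left": filled["heel_l_x"], "right": filled["heel_r_x"]}
    channels: dict = {
        "com_pos": (t_m, com.position),
        "com_vel": (t_m, com.velocity),
        "cop": (t_m, cop),
        "cop_rel": (t_m, cop_rel),
        "stance_heel_x": (t_m, heel_x),
        "swing_heel_x": (t_m, heel_x),
    }
    if "heel_l_y" in filled:
        heel_y = {"left": filled["heel_l_y"], "right": filled["heel_r_y"]}
        channels["stance_heel_y"] = (t_m, heel_y)
        channels["swing_heel_y"] = (t_m, heel_y)
    if bundle.angles is not None:
        for chan, base in _ANGLE_CHANNELS.items():
            if f"{base}_l" in bundle.angles.columns:
                sides = {
                    "left": pp.lowpass(bundle.angles[f"{base}_l"].to_numpy(), fs_m, opt.fc_kinematics_hz),
                    "right": pp.lowpass(bundle.angles[f"{base}_r"].to_numpy(), fs_m, opt.fc_kinematics_hz),
                }
                channels[chan] = (t_m, sides)
    for chan, muscle in _EMG_CHANNELS.items():
        if muscle in emg_norm:
            channels[chan] = (t_m, emg_norm[muscle])

    # --- records ----------------------------------------------------------
    records = st.segment_and_select(
        heelstrikes, pushoffs, stimuli, channels, subject=subject, excluded_times=excluded_times
    )
    for rec in records:
        if rec.traj and "swing_heel_x" in rec.traj:
            rec.traj["rel_heel_x"] = rec.traj["swing_heel_x"] - rec.traj["stance_heel_x"]

    controls = [r for r in records if r.condition == "control"]
    responses = st.baseline_subtract(records, controls)

    # label and mirror all stimulus-associated responses
    labeled: list[st.StepRecord] = []
    for rec in responses:
        if rec.stimulus_id is not None:
            rec = st.classify_and_mirror(rec, stimuli[rec.stimulus_id])
        labeled.append(rec)
    control_responses = [r for r in labeled if r.condition == "control" and not r.excluded]
    stim_responses = [r for r in labeled if r.condition in ("toward", "away")]

    # --- foot-placement model and outcomes --------------------------------
    fp_model = None
    try:
        fp_model = st.fit_foot_placement_model(
            control_responses, min_steps=opt.min_control_steps,
            midstance_fraction=opt.midstance_fraction,
        )
    except ValueError:
        pass
    outcome_rows = []
    for rec in stim_responses:
        if rec.step_index == 1 and not rec.excluded:
            outcome_rows.append(st.compute_outcomes(rec, fp_model))
    outcomes = st.outcomes_frame(outcome_rows) if outcome_rows else pd.DataFrame()

    reasons: dict[str, int] = {}
    for rec in records:
        if rec.excluded:
            reasons[rec.exclusion_reason] = reasons.get(rec.exclusion_reason, 0) + 1
    return TrialAnalysis(
        subject=subject,
        heelstrikes=heelstrikes,
        pushoffs=pushoffs,
        stimuli=stimuli,
        records=records,
        responses=labeled,
        control_responses=control_responses,
        fp_model=fp_model,
        outcomes=outcomes,
        n_excluded=sum(reasons.values()),
        exclusion_reasons=reasons,
    )


def pooled_onsets(
    analyses: list[TrialAnalysis],
    variables: tuple[str, ...] = ("cop", "rel_heel_x"),
    by_condition: bool = False,
) -> dict[str, st.OnsetEstimate]:
    """Onset estimates from step +1 responses pooled across trials.

    By default toward- and away-responses are pooled after flipping the
    away responses' sign (the generator and, by the symmetry assumption,
    the walker respond mirror-symmetrically); with ``by_condition`` the
    two directions are estimated separately.
    """
    out: dict[str, st.OnsetEstimate] = {}
    step1 = [
        r
        for a in analyses
        for r in a.responses
        if r.step_index == 1 and not r.excluded and r.condition in ("toward", "away")
    ]
    if not step1:
        return out
    conditions = ("toward", "away") if by_condition else ("pooled",)
    for var in variables:
        # spatial responses are negative for away stimuli, body-relative
        # ones for toward stimuli; flip that side before pooling
        flip_cond = "away" if var in st.SPATIAL_CHANNELS else "toward"
        for cond in conditions:
            chosen = []
            durations = []
            for r in step1:
                if var not in r.traj:
                    continue
                if cond != "pooled" and r.condition != cond:
                    continue
                y = r.traj[var]
                if cond == "pooled" and r.condition == flip_cond:
                    y = -y
                chosen.append(y)
                durations.append(r.duration)
            if len(chosen) < 2:
                continue
            est = st.estimate_onset(
                np.array(chosen), float(np.mean(durations)), variable=var, condition=cond
            )
            out[f"{var}:{cond}"] = est
    return out


def recovery_study(
    n_trials: int = 50,
    n_steps: int = 170,
    base_seed: int = 0,
    config_kwargs: dict | None = None,
) -> dict:
    """Parameter-recovery study: generate seeded trials, run the full
    pipeline, and compare the recovered stimulus-induced foot-placement
    shift and response onsets against the generator's ground truth.

    Onsets are estimated from the step +1 responses pooled across all
    trials (sign-adjusted across directions), mirroring how responses
    are pooled across repeats within a study.
    """
    import warnings

    from .synthetic import WalkerConfig, generate_trial

    kwargs = config_kwargs or {}
    analyses = []
    truths = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_trials):
            seed = (base_seed + i * 9973) % (2**31 - 1)
            cfg = WalkerConfig(seed=seed, **kwargs)
            bundle, truth = generate_trial(cfg, n_steps=n_steps)
            analyses.append(analyze_trial(bundle))
            truths.append(truth)
    fp_vals = np.concatenate(
        [a.outcomes["stimulus_induced_fp_change"].to_numpy() for a in analyses if len(a.outcomes)]
    )
    true_gain = truths[0].gains["fp_shift_mm"]
    onsets = pooled_onsets(analyses, variables=("cop", "rel_heel_x"))
    cop_est = onsets["cop:pooled"].onset_ms
    fp_est = onsets["rel_heel_x:pooled"].onset_ms
    return {
        "n_trials": n_trials,
        "n_stimulus_steps": int(len(fp_vals)),
        "fp_gain_true_mm": float(true_gain),
        "fp_gain_recovered_mm": float(np.mean(fp_vals)),
        "fp_gain_bias_mm": float(np.mean(fp_vals) - true_gain),
        "cop_onset_true_ms": float(truths[0].onsets_ms["cop"]),
        "cop_onset_recovered_ms": float(cop_est) if cop_est is not None else None,
        "fp_onset_true_ms": float(truths[0].onsets_ms["foot_placement"]),
        "fp_onset_recovered_ms": float(fp_est) if fp_est is not None else None,
    }
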