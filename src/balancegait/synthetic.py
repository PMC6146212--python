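"""Synthetic treadmill walker with known ground truth.

The walker is kinematic: marker, force-plate, joint-angle and EMG streams
are prescribed trajectories with the statistical structure the analysis
chain expects, not the output of a dynamic simulation.  This makes every
injected quantity (gait event times, foot-placement law coefficients,
stimulus response gains and onset latencies) exactly known, so the whole
downstream pipeline can be validated by parameter recovery.

Key constructions
-----------------
* Heel height is ``|sin|`` of stride phase: sharp minima exactly at the
  true heelstrikes, prominence well above the detection threshold.
* 2nd-metatarsal height is a smooth swing bump whose maximum upward
  velocity falls exactly at the true pushoff time.
* Lateral CoM is a stride-locked sway plus a smooth stochastic component
  built as a cubic Hermite interpolant through independent (position,
  velocity) draws at each step's midstance, so the CoM state at midstance
  is exactly the drawn value and is serially uncorrelated across steps.
* Each foot placement follows the linear CoM-state law
  ``placement = stance + base + c_pos * com_pos(mid) + c_vel * com_vel(mid)
  + stimulus shift + noise`` exactly, so regression on control steps
  recovers ``(c_pos, c_vel)`` and the stimulus steps carry the injected
  foot-placement shift.
* Stimulus responses (CoP shift, foot-placement shift, angle and EMG
  modulation) ramp in linearly at their configured onsets with a smooth
  saturation, so the tangent-extrapolation onset estimator has the onset
  itself as its exact target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .io import ANALOG_FS, MARKER_FS, TrialBundle
from .stimulus import RotationProfileParams, StimulusEvent, schedule_stimuli, stimulus_log_frame

__all__ = ["WalkerConfig", "GroundTruth", "generate_trial"]

SEGMENT_NAMES = (
    "pelvis",
    "torso",
    "head",
    "thigh_left",
    "thigh_right",
    "shank_left",
    "shank_right",
    "foot_left",
    "foot_right",
    "arm_left",
    "arm_right",
)

EMG_MUSCLES = (
    "gluteus_medius",
    "tensor_fasciae_latae",
    "gastrocnemius_medialis",
    "tibialis_anterior",
    "peroneus_longus",
)

# burst centre (stride phase) and concentration for each muscle envelope
_EMG_BURSTS = {
    "gluteus_medius": (0.10, 8.0),
    "tensor_fasciae_latae": (0.15, 8.0),
    "gastrocnemius_medialis": (0.55, 10.0),
    "tibialis_anterior": (0.02, 10.0),
    "peroneus_longus": (0.50, 8.0),
}


@dataclass(frozen=True)
class WalkerConfig:
    """Study conditions emulated by the synthetic walker.

    Cadence follows the 90 steps/min metronome (step period 0.667 s).
    Response gains and onsets are the quantities the pipeline is asked to
    recover; noise magnitudes are fixed, realistic defaults.
    """

    # gait geometry / timing
    step_period: float = 0.667  # s (90 steps/min)
    step_width: float = 100.0  # mm between left/right base placements
    double_stance: float = 0.15  # s, weight-transfer duration
    belt_speed: float = 900.0  # mm/s, anterior heel drift during stance

    # CoM construction
    sway_amplitude: float = 20.0  # mm, stride-locked lateral sway
    com_pos_sd: float = 3.0  # mm, midstance CoM position deviations
    com_vel_sd: float = 10.0  # mm/s, midstance CoM velocity deviations

    # foot-placement law (per-subject ground truth coefficients)
    fp_coeff_pos: float = 1.0  # mm per mm of CoM midstance position
    fp_coeff_vel: float = 0.15  # mm per mm/s of CoM midstance velocity
    fp_noise_sd: float = 2.0  # mm, placement noise

    # injected stimulus responses
    cop_shift_gain: float = 8.0  # mm, CoP shift in the fall direction
    response_onset_cop: float = 0.300  # s after the trigger
    cop_ramp: float = 0.200  # s, linear rise time of the CoP shift
    fp_shift_gain: float = 5.0  # mm, foot-placement shift in fall direction
    response_onset_fp: float = 0.420  # s after the trigger
    fp_ramp: float = 0.220  # s; linear long enough to clear the 10 Hz kernel
    eversion_gain: float = 0.5  # deg, stance ankle eversion (away) / inversion (toward)
    eversion_onset: float = 0.340  # s
    pushoff_gain: float = 2.0  # deg, trailing-leg plantarflexion modulation
    pushoff_onset: float = 0.420  # s
    hip_abduction_gain: float = 0.15  # deg, swing hip ab-/adduction modulation
    hip_abduction_onset: float = 0.550  # s
    emg_gain_pl: float = 0.15  # fractional peroneus longus modulation
    emg_gain_gm: float = 0.05  # fractional gluteus medius modulation
    emg_gain_gastroc: float = 0.10  # fractional gastrocnemius modulation
    emg_onset: float = 0.200  # s
    response_hold: float = 1.4  # s of sustained response after the trigger
    response_decay: float = 0.3  # s fade-out after the hold

    # noise and artifacts
    marker_noise_sd: float = 0.5  # mm
    angle_noise_sd: float = 0.05  # deg
    emg_noise_sd: float = 0.05  # a.u.; 0 switches to deterministic envelopes
    moment_noise_sd: float = 0.7  # N*m on plate moments
    gap_rate: float = 0.0  # marker dropouts per second per channel
    gap_mean_ms: float = 60.0  # mean dropout length (geometric)

    seed: int = 0
    subject: str = "S01"

    def __post_init__(self) -> None:
        if self.step_period <= 0:
            raise ValueError("step_period must be positive")
        for name in ("marker_noise_sd", "emg_noise_sd", "fp_noise_sd", "moment_noise_sd",
                     "angle_noise_sd", "gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("cop_shift_gain", "fp_shift_gain", "pushoff_gain", "eversion_gain",
                     "fp_coeff_pos", "fp_coeff_vel"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("response_onset_cop", "response_onset_fp"):
            onset = getattr(self, name)
            if not 0 <= onset <= 2 * self.step_period:
                raise ValueError(f"{name} must lie within [0, 2*step_period]")


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery tests."""

    heelstrike_times: np.ndarray  # s, all feet interleaved
    heelstrike_feet: np.ndarray  # "left"/"right" per heelstrike
    pushoff_times: np.ndarray  # s, pushoff of the foot landing at hs[k] (k>=1)
    pushoff_feet: np.ndarray
    placements: np.ndarray  # mm, lateral landing position per heelstrike
    com_mid_pos: np.ndarray  # mm, CoM position deviation at midstance of step k->k+1
    com_mid_vel: np.ndarray  # mm/s
    fp_coeff_pos: float
    fp_coeff_vel: float
    onsets_ms: dict  # injected onsets, ms after the trigger
    gains: dict
    stimuli: list[StimulusEvent]
    step_table: pd.DataFrame  # t_start, t_end, stance_foot, swing_foot, fp_true


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


_RAMP_LIN_END = 0.6  # end of the exactly-linear part (normalized time)
_RAMP_SLOPE = 1.0 / 0.85  # slope of the linear part
_RAMP_BLEND = 0.25  # half-width of the symmetric corner blend at the onset


def _onset_ramp(u) -> np.ndarray:
    """Monotone 0->1 ramp whose linear part backward-extrapolates to u=0.

    The onset corner is smoothed symmetrically (quadratic blend over
    [-blend, +blend]), so zero-phase low-pass filtering does not ring at
    the corner; the smoothing is symmetric about the nominal onset, so
    the tangent-intersection estimator's target remains exactly u=0.
    The ramp then saturates through a cubic Hermite blend."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    d = _RAMP_BLEND
    corner = (u > -d) & (u <= d)
    out[corner] = _RAMP_SLOPE * (u[corner] + d) ** 2 / (4.0 * d)
    lin = (u > d) & (u <= _RAMP_LIN_END)
    out[lin] = _RAMP_SLOPE * u[lin]
    blend = (u > _RAMP_LIN_END) & (u < 1.0)
    if np.any(blend):
        du = 1.0 - _RAMP_LIN_END
        s = (u[blend] - _RAMP_LIN_END) / du
        p0 = _RAMP_SLOPE * _RAMP_LIN_END
        m0 = _RAMP_SLOPE * du
        h00 = 2 * s**3 - 3 * s**2 + 1
        h10 = s**3 - 2 * s**2 + s
        h01 = -2 * s**3 + 3 * s**2
        out[blend] = h00 * p0 + h10 * m0 + h01 * 1.0
    out[u >= 1.0] = 1.0
    return out


def _injection(t: np.ndarray, t_trig: float, onset: float, ramp: float,
               hold: float, decay: float) -> np.ndarray:
    """Injected response time course: ramp in at t_trig+onset, hold, fade."""
    rise = _onset_ramp((t - t_trig - onset) / ramp)
    fade = 1.0 - _smoothstep((t - t_trig - hold) / decay)
    return rise * fade


def _geometric_gap_lengths(rng: np.random.Generator, n: int, mean_samples: float) -> np.ndarray:
    p = min(1.0, 1.0 / max(mean_samples, 1.0))
    return rng.geometric(p, size=n)


def generate_trial(
    config: WalkerConfig,
    n_steps: int = 60,
    stimuli: list[StimulusEvent] | str | None = "auto",
) -> tuple[TrialBundle, GroundTruth]:
    """Generate one walking block and its ground truth.

    ``stimuli`` may be "auto" (schedule with the default washout on the
    true heelstrikes), an explicit list of :class:`StimulusEvent`, or
    None/[] for an unperturbed block.  Stimuli whose four-step analysis
    window would extend past the trial end are dropped with a warning.
    All randomness derives from ``config.seed``.
    """
    if n_steps < 6:
        raise ValueError("need at least 6 steps (4 post-stimulus + 2 control)")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    T = cfg.step_period
    stride = 2.0 * T
    dds = cfg.double_stance
    warm = 1.0
    dur = warm + (n_steps - 1) * T + 0.8

    # --- true gait events -------------------------------------------------
    hs_times = warm + T * np.arange(n_steps)
    hs_feet = np.array(["left", "right"] * ((n_steps + 1) // 2))[:n_steps].astype(object)
    # pushoff of the foot landing at hs[k] happens dds after hs[k-1]
    po_times = hs_times[:-1] + dds
    po_feet = hs_feet[1:].copy()

    # --- stimuli ----------------------------------------------------------
    if isinstance(stimuli, str) and stimuli == "auto":
        sched_seed = int(rng.integers(0, 2**31 - 1))
        stim_list = schedule_stimuli(hs_times, hs_feet, seed=sched_seed)
    elif stimuli is None:
        stim_list = []
    else:
        stim_list = list(stimuli)
    kept: list[StimulusEvent] = []
    for ev in stim_list:
        k = int(np.argmin(np.abs(hs_times - ev.trigger_time)))
        if abs(hs_times[k] - ev.trigger_time) > 1e-6:
            raise ValueError("stimulus trigger does not coincide with a true heelstrike")
        if k + 4 >= n_steps or k < 2:
            warnings.warn("stimulus too close to trial boundary; dropped", stacklevel=2)
            continue
        kept.append(ev)
    stim_list = kept
    trigger_steps = {}  # heelstrike index of trigger -> StimulusEvent
    for ev in stim_list:
        trigger_steps[int(round((ev.trigger_time - warm) / T))] = ev

    # --- time bases -------------------------------------------------------
    t_m = np.arange(0.0, dur, 1.0 / MARKER_FS)
    t_a = np.arange(0.0, dur, 1.0 / ANALOG_FS)

    # --- CoM: stride-locked sway + Hermite noise through midstance knots --
    n_mid = n_steps - 1
    mid_times = hs_times[:-1] + 0.5 * T
    p_knots = rng.normal(0.0, cfg.com_pos_sd, size=n_mid)
    v_knots = rng.normal(0.0, cfg.com_vel_sd, size=n_mid)
    knot_t = np.concatenate(([0.0], mid_times, [dur]))
    knot_p = np.concatenate(([0.0], p_knots, [0.0]))
    knot_v = np.concatenate(([0.0], v_knots, [0.0]))
    com_noise = CubicHermiteSpline(knot_t, knot_p, knot_v)
    # sway: leftmost (negative x) at midstance of left-stance steps
    # left foot lands at hs[0], so left single stance is centred on mid_times[0]
    sway_phase = 2.0 * np.pi * (t_m - mid_times[0]) / stride
    com_x = -cfg.sway_amplitude * np.cos(sway_phase) + com_noise(t_m)

    # --- foot placements via the linear CoM-state law ---------------------
    dir_signs = {"left": -1.0, "right": 1.0}
    placements = np.zeros(n_steps)
    base = {"left": -cfg.step_width / 2.0, "right": cfg.step_width / 2.0}
    placements[0] = base[hs_feet[0]]
    fp_noise = rng.normal(0.0, cfg.fp_noise_sd, size=n_steps)
    fp_true = np.full(n_steps, np.nan)  # relative placement of step k-1 -> k
    stim_fp_offset = np.zeros(n_steps)
    for k in range(1, n_steps):
        foot = hs_feet[k]
        base_diff = base[foot] - base[hs_feet[k - 1]]
        law = (
            cfg.fp_coeff_pos * p_knots[k - 1]
            + cfg.fp_coeff_vel * v_knots[k - 1]
            + (fp_noise[k] if cfg.fp_noise_sd > 0 else 0.0)
        )
        if (k - 1) in trigger_steps:  # landing ends step +1 of this stimulus
            ev = trigger_steps[k - 1]
            stim_fp_offset[k] = dir_signs[ev.direction] * cfg.fp_shift_gain
        placements[k] = placements[k - 1] + base_diff + law + stim_fp_offset[k]
        fp_true[k] = placements[k] - placements[k - 1]

    # --- heel trajectories ------------------------------------------------
    heel_amp = 80.0
    markers: dict[str, np.ndarray] = {}
    heel_x = {}
    heel_y = {}
    y_land = 300.0
    for foot in ("left", "right"):
        own = np.flatnonzero(hs_feet == foot)
        first_hs = hs_times[own[0]]
        last_hs = hs_times[own[-1]]
        # clamp the phase half a stride beyond the first/last heelstrike so
        # the periodic pattern produces no spurious minima at the trial edges
        t_clamped = np.clip(t_m, first_hs - stride / 2.0, last_hs + stride / 2.0)
        phase = (t_clamped - first_hs) / stride
        markers[f"heel_{foot[0]}_z"] = heel_amp * np.abs(np.sin(np.pi * phase))
        x = np.full_like(t_m, placements[own[0]])
        y = np.full_like(t_m, y_land)
        for j, k in enumerate(own):
            hs_k = hs_times[k]
            # stance: constant lateral position, anterior belt drift
            stance_end = hs_times[k + 1] + dds if k + 1 < n_steps else dur
            sl = (t_m >= hs_k) & (t_m < stance_end)
            x[sl] = placements[k]
            y[sl] = y_land - cfg.belt_speed * (t_m[sl] - hs_k)
            # swing toward the next landing of this foot
            if k + 2 < n_steps:
                land = hs_times[k + 2]
                sw = (t_m >= stance_end) & (t_m < land)
                u = (t_m[sw] - stance_end) / (land - stance_end)
                target = placements[k + 2] - stim_fp_offset[k + 2]
                x[sw] = placements[k] + (target - placements[k]) * _smoothstep(u)
                y_off = y_land - cfg.belt_speed * (stance_end - hs_times[k + 1] + T)
                y[sw] = y_off + (y_land - y_off) * _smoothstep(u)
                if stim_fp_offset[k + 2] != 0.0:
                    ev = trigger_steps[k + 1]
                    x[sw] += (
                        dir_signs[ev.direction]
                        * cfg.fp_shift_gain
                        * _onset_ramp((t_m[sw] - ev.trigger_time - cfg.response_onset_fp) / cfg.fp_ramp)
                    )
                x[t_m >= land] = placements[k + 2]
            else:
                x[t_m >= stance_end] = placements[k]
                y[t_m >= stance_end] = y_land - cfg.belt_speed * (stance_end - hs_k)
        heel_x[foot] = x
        heel_y[foot] = y
        markers[f"heel_{foot[0]}_x"] = x.copy()
        markers[f"heel_{foot[0]}_y"] = y.copy()

    # --- 2nd metatarsal: swing bump, max upward velocity at true pushoff --
    bump_width = 0.4
    bump_amp = 60.0
    for foot in ("left", "right"):
        z = np.zeros_like(t_m)
        for k, po in enumerate(po_times):
            if po_feet[k] != foot:
                continue
            u = (t_m - (po - 0.25 * bump_width)) / bump_width
            in_b = (u > 0) & (u < 1)
            z[in_b] += bump_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[in_b]))
        markers[f"met2_{foot[0]}_z"] = z

    # --- segment CoM markers (weighted mean identical to com_x) -----------
    from .preprocess import DEFAULT_SEGMENT_FRACTIONS

    wiggle = 2.0 * np.sin(2.0 * np.pi * t_m / stride)
    w_pelvis = DEFAULT_SEGMENT_FRACTIONS["pelvis"]
    w_torso = DEFAULT_SEGMENT_FRACTIONS["torso"]
    for name in SEGMENT_NAMES:
        if name == "pelvis":
            markers[f"{name}_x"] = com_x + wiggle
        elif name == "torso":
            markers[f"{name}_x"] = com_x - wiggle * w_pelvis / w_torso
        else:
            markers[f"{name}_x"] = com_x.copy()

    # --- force plates -----------------------------------------------------
    body_fz = 700.0
    load = {"left": np.zeros_like(t_a), "right": np.zeros_like(t_a)}
    # before the first heelstrike the contralateral foot carries the load
    pre_foot = "right" if hs_feet[0] == "left" else "left"
    load[pre_foot][t_a < hs_times[0]] = 1.0
    for k in range(n_steps):
        foot = hs_feet[k]
        other = "right" if foot == "left" else "left"
        ramp = np.clip((t_a - hs_times[k]) / dds, 0.0, 1.0)
        after = t_a >= hs_times[k]
        load[foot][after] = ramp[after]
        load[other][after] = 1.0 - ramp[after]
    fz = {f: body_fz * load[f] for f in ("left", "right")}

    plate_origins = {"left": -200.0, "right": 200.0}
    # plate CoP sits at the side's base position with a small stride-locked
    # progression; decoupled from the slowly drifting placements so the
    # injected shift is the only stimulus-locked CoP component
    cop_plate = {}
    for foot in ("left", "right"):
        own = np.flatnonzero(hs_feet == foot)
        phase_f = 2.0 * np.pi * (t_a - hs_times[own[0]]) / stride
        cop_plate[foot] = base[foot] + 5.0 * np.sin(phase_f)
    for ev in stim_list:
        inj = _injection(t_a, ev.trigger_time, cfg.response_onset_cop, cfg.cop_ramp,
                         cfg.response_hold, cfg.response_decay)
        cop_plate[ev.trigger_foot] += dir_signs[ev.direction] * cfg.cop_shift_gain * inj

    forces = {"time_s": t_a}
    for foot in ("left", "right"):
        mx = fz[foot] * (cop_plate[foot] - plate_origins[foot]) / 1000.0
        if cfg.moment_noise_sd > 0:
            mx = mx + rng.normal(0.0, cfg.moment_noise_sd, size=len(t_a))
        forces[f"fz_{foot[0]}"] = fz[foot]
        forces[f"mx_{foot[0]}"] = mx

    # --- joint angles -----------------------------------------------------
    angles: dict[str, np.ndarray] = {}
    base_patterns = {
        "ankle_eversion": (3.0, 0.5),
        "ankle_plantarflexion": (10.0, 2.0),
        "hip_abduction": (5.0, 1.0),
        "hip_rotation": (4.0, 2.5),
        "knee_rotation": (4.0, 4.0),
    }
    for foot in ("left", "right"):
        own = np.flatnonzero(hs_feet == foot)
        first_hs = hs_times[own[0]]
        phase = 2.0 * np.pi * (t_m - first_hs) / stride
        for name, (amp, ph) in base_patterns.items():
            angles[f"{name}_{foot[0]}"] = amp * np.sin(phase + ph)
    for ev in stim_list:
        trig = ev.trigger_foot
        swing = "right" if trig == "left" else "left"
        toward = ev.direction == ev.trigger_foot
        s_body = -1.0 if toward else 1.0  # eversion/abduction sign convention
        t0 = ev.trigger_time
        ev_inj = _injection(t_m, t0, cfg.eversion_onset, 0.20, cfg.response_hold, cfg.response_decay)
        angles[f"ankle_eversion_{trig[0]}"] += s_body * cfg.eversion_gain * ev_inj
        po_inj = _injection(t_m, t0, cfg.pushoff_onset, 0.20, cfg.response_hold, cfg.response_decay)
        angles[f"ankle_plantarflexion_{trig[0]}"] += -s_body * cfg.pushoff_gain * po_inj
        hip_inj = _injection(t_m, t0, cfg.hip_abduction_onset, 0.20, cfg.response_hold, cfg.response_decay)
        angles[f"hip_abduction_{swing[0]}"] += s_body * cfg.hip_abduction_gain * hip_inj
        angles[f"hip_rotation_{swing[0]}"] += s_body * 0.5 * hip_inj
        angles[f"knee_rotation_{trig[0]}"] += -s_body * 0.5 * hip_inj

    # --- EMG ----------------------------------------------------------------
    emg: dict[str, np.ndarray] = {"time_s": t_a}
    emg_gains = {
        "peroneus_longus": cfg.emg_gain_pl,
        "gluteus_medius": cfg.emg_gain_gm,
        "gastrocnemius_medialis": cfg.emg_gain_gastroc,
    }
    for foot in ("left", "right"):
        own = np.flatnonzero(hs_feet == foot)
        first_hs = hs_times[own[0]]
        phase = ((t_a - first_hs) / stride) % 1.0
        for muscle in EMG_MUSCLES:
            centre, kappa = _EMG_BURSTS[muscle]
            env = 0.1 + np.exp(kappa * (np.cos(2.0 * np.pi * (phase - centre)) - 1.0))
            for ev in stim_list:
                toward = ev.direction == ev.trigger_foot
                trig = ev.trigger_foot
                swing = "right" if trig == "left" else "left"
                mod = 0.0
                if muscle == "peroneus_longus" and foot == trig:
                    mod = (1.0 if not toward else -1.0) * emg_gains[muscle]
                elif muscle == "gastrocnemius_medialis" and foot == trig:
                    mod = (1.0 if toward else -1.0) * emg_gains[muscle]
                elif muscle == "gluteus_medius" and foot == swing:
                    mod = (1.0 if not toward else -1.0) * emg_gains[muscle]
                if mod:
                    inj = _injection(t_a, ev.trigger_time, cfg.emg_onset, 0.15,
                                     cfg.response_hold, cfg.response_decay)
                    env = env * (1.0 + mod * inj)
            if cfg.emg_noise_sd > 0:
                raw = env * rng.standard_normal(len(t_a)) + cfg.emg_noise_sd * rng.standard_normal(len(t_a))
            else:
                raw = env
            emg[f"{muscle}_{foot[0]}"] = raw

    # --- noise and marker dropouts ---------------------------------------
    if cfg.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, cfg.marker_noise_sd, size=len(t_m))
    if cfg.angle_noise_sd > 0:
        for name in angles:
            angles[name] = angles[name] + rng.normal(0.0, cfg.angle_noise_sd, size=len(t_m))
    if cfg.gap_rate > 0:
        mean_samples = cfg.gap_mean_ms * MARKER_FS / 1000.0
        for name in markers:
            n_gaps = rng.poisson(cfg.gap_rate * dur)
            if n_gaps == 0:
                continue
            starts = rng.integers(0, len(t_m), size=n_gaps)
            lengths = _geometric_gap_lengths(rng, n_gaps, mean_samples)
            for s0, ln in zip(starts, lengths):
                markers[name][s0 : s0 + int(ln)] = np.nan

    # --- bundle -----------------------------------------------------------
    markers_df = pd.DataFrame({"time_s": t_m, **markers})
    angles_df = pd.DataFrame({"time_s": t_m, **angles})
    forces_df = pd.DataFrame(forces)
    emg_df = pd.DataFrame(emg)
    stim_df = stimulus_log_frame(stim_list)
    meta = {
        "subject": cfg.subject,
        "marker_fs_hz": MARKER_FS,
        "analog_fs_hz": ANALOG_FS,
        "plate_origins_mm": {"left": plate_origins["left"], "right": plate_origins["right"]},
        "standing_heel_height_mm": {"left": 28.0, "right": 28.0},
        "marker_names": sorted({c[:-2] for c in markers_df.columns if c != "time_s"}),
    }
    bundle = TrialBundle(
        markers=markers_df,
        forces=forces_df,
        emg=emg_df,
        stimulus_log=stim_df,
        meta=meta,
        angles=angles_df,
    )

    step_table = pd.DataFrame(
        {
            "t_start": hs_times[:-1],
            "t_end": hs_times[1:],
            "stance_foot": hs_feet[:-1],
            "swing_foot": hs_feet[1:],
            "fp_true": fp_true[1:],
            "stim_fp_offset": stim_fp_offset[1:],
        }
    )
    truth = GroundTruth(
        heelstrike_times=hs_times,
        heelstrike_feet=hs_feet,
        pushoff_times=po_times,
        pushoff_feet=po_feet,
        placements=placements,
        com_mid_pos=p_knots,
        com_mid_vel=v_knots,
        fp_coeff_pos=cfg.fp_coeff_pos,
        fp_coeff_vel=cfg.fp_coeff_vel,
        onsets_ms={
            "cop": cfg.response_onset_cop * 1000.0,
            "foot_placement": cfg.response_onset_fp * 1000.0,
            "eversion": cfg.eversion_onset * 1000.0,
            "pushoff": cfg.pushoff_onset * 1000.0,
            "emg": cfg.emg_onset * 1000.0,
        },
        gains={
            "cop_shift_mm": cfg.cop_shift_gain,
            "fp_shift_mm": cfg.fp_shift_gain,
            "eversion_deg": cfg.eversion_gain,
            "pushoff_deg": cfg.pushoff_gain,
        },
        stimuli=stim_list,
        step_table=step_table,
    )
    return bundle, truth
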