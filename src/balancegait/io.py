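"""On-disk trial format and the synchronized TrialBundle container.

A trial is a directory of plain delimited tables plus a YAML sidecar:

    markers.csv   time_s + one column per marker coordinate (mm, 250 Hz)
    forces.csv    time_s + per-plate vertical force (N) and moment (N*m), 1000 Hz
    emg.csv       time_s + one column per EMG channel (a.u., 1000 Hz)
    angles.csv    time_s + one column per joint angle (deg, 250 Hz; optional)
    stimuli.csv   time_s, trigger_foot, direction, peak_angle_deg
    meta.yaml     subject id, sampling rates, declared channel sets,
                  standing heel heights, plate origins

All streams share the common time origin t=0.  NaN encodes occluded
samples; the round trip is lossless for finite values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["TrialBundle", "read_trial", "write_trial"]

MARKER_FS = 250.0
ANALOG_FS = 1000.0


@dataclass
class TrialBundle:
    """Synchronized streams for one walking block.

    markers : DataFrame, ``time_s`` plus marker coordinate columns (mm)
    forces : DataFrame, ``time_s`` plus per-plate ``fz_*`` (N) / ``mx_*`` (N*m)
    emg : DataFrame, ``time_s`` plus EMG channels (a.u.)
    angles : DataFrame or None, ``time_s`` plus joint-angle channels (deg)
    stimulus_log : DataFrame (time_s, trigger_foot, direction, peak_angle_deg)
    meta : dict with subject, rates, channel declarations, calibration
    """

    markers: pd.DataFrame
    forces: pd.DataFrame
    emg: pd.DataFrame
    stimulus_log: pd.DataFrame
    meta: dict
    angles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.meta.setdefault("marker_fs_hz", MARKER_FS)
        self.meta.setdefault("analog_fs_hz", ANALOG_FS)
        for name in ("marker_fs_hz", "analog_fs_hz"):
            if self.meta[name] <= 0:
                raise ValueError(f"{name} must be positive")
        declared = self.meta.get("marker_names")
        if declared is not None:
            have = {c[:-2] for c in self.markers.columns if c != "time_s"}
            missing = set(declared) - have
            if missing:
                raise ValueError(f"markers stream missing declared marker(s): {sorted(missing)}")

    @property
    def marker_fs(self) -> float:
        return float(self.meta["marker_fs_hz"])

    @property
    def analog_fs(self) -> float:
        return float(self.meta["analog_fs_hz"])


_STREAMS = ("markers", "forces", "emg", "stimuli", "meta")


def write_trial(bundle: TrialBundle, path) -> Path:
    """Write a TrialBundle to a directory of delimited tables + YAML sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"  # full double precision: the round trip is bit-lossless
    bundle.markers.to_csv(path / "markers.csv", index=False, float_format=fmt)
    bundle.forces.to_csv(path / "forces.csv", index=False, float_format=fmt)
    bundle.emg.to_csv(path / "emg.csv", index=False, float_format=fmt)
    bundle.stimulus_log.to_csv(path / "stimuli.csv", index=False, float_format=fmt)
    if bundle.angles is not None:
        bundle.angles.to_csv(path / "angles.csv", index=False, float_format=fmt)
    meta = _yaml_safe(bundle.meta)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_trial(path) -> TrialBundle:
    """Read a trial directory written by :func:`write_trial`.

    A missing mandatory stream raises a FileNotFoundError naming it; a
    sampling-rate mismatch between the sidecar and the time vectors raises
    a ValueError.
    """
    path = Path(path)
    for stream, fname in [
        ("markers", "markers.csv"),
        ("forces", "forces.csv"),
        ("emg", "emg.csv"),
        ("stimuli", "stimuli.csv"),
        ("meta", "meta.yaml"),
    ]:
        if not (path / fname).exists():
            raise FileNotFoundError(f"trial at {path} is missing the '{stream}' stream ({fname})")
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    # round_trip parsing: together with the %.17g writer the on-disk
    # format is bit-lossless for finite doubles
    read = lambda p: pd.read_csv(p, float_precision="round_trip")
    markers = read(path / "markers.csv")
    forces = read(path / "forces.csv")
    emg = read(path / "emg.csv")
    stimuli = read(path / "stimuli.csv")
    angles_path = path / "angles.csv"
    angles = read(angles_path) if angles_path.exists() else None

    _check_rate(markers, meta.get("marker_fs_hz", MARKER_FS), "markers")
    _check_rate(forces, meta.get("analog_fs_hz", ANALOG_FS), "forces")
    _check_rate(emg, meta.get("analog_fs_hz", ANALOG_FS), "emg")
    return TrialBundle(
        markers=markers, forces=forces, emg=emg, stimulus_log=stimuli, meta=meta, angles=angles
    )


def _check_rate(frame: pd.DataFrame, fs: float, name: str, rtol: float = 1e-3) -> None:
    if "time_s" not in frame.columns:
        raise ValueError(f"{name} stream has no time_s column")
    t = frame["time_s"].to_numpy()
    if len(t) < 2:
        return
    dt = np.median(np.diff(t))
    if abs(dt * fs - 1.0) > rtol:
        raise ValueError(
            f"{name} stream sampling rate mismatch: sidecar declares {fs} Hz "
            f"but time vector spacing implies {1.0 / dt:.3f} Hz"
        )


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_yaml_safe(v) for v in obj.tolist()]
    return obj
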