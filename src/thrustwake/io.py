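"""Readers/writers for midline tracks and velocity-field sequences.

On-disk dialects (SI units everywhere, comma-separated, '.' decimal,
mandatory header, UTF-8):

* Midline track CSV: columns ``frame`` (int), ``time_s``, ``marker``
  (int, 0 = snout ... n-1 = tail tip), ``x_m``, ``y_m``.
* Velocity-field sequence: one CSV per frame (``frame_0000.csv`` ...)
  with columns ``x_m, y_m, u_mps, v_mps, mask`` plus a ``meta.json``
  sidecar carrying ``dt_s``, ``U_inf_mps``, ``rho_kgpm3`` and the grid
  dimensions; alternatively a single HDF5 container with the same named
  arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .kinematics import MidlineTrack
from .synth import VelocityFieldSequence

__all__ = [
    "load_midline_csv",
    "write_midline_csv",
    "load_field_sequence",
    "write_field_sequence",
    "load_field_sequence_h5",
    "write_field_sequence_h5",
    "RunConfig",
    "load_config",
]

MIDLINE_COLUMNS = ["frame", "time_s", "marker", "x_m", "y_m"]
FIELD_COLUMNS = ["x_m", "y_m", "u_mps", "v_mps", "mask"]


def write_midline_csv(track: MidlineTrack, path) -> Path:
    path = Path(path)
    nf, nm = track.n_frames, track.n_markers
    frames = np.repeat(np.arange(nf), nm)
    markers = np.tile(np.arange(nm), nf)
    df = pd.DataFrame({
        "frame": frames,
        "time_s": np.repeat(track.times, nm),
        "marker": markers,
        "x_m": track.xy[:, :, 0].ravel(),
        "y_m": track.xy[:, :, 1].ravel(),
    })
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_midline_csv(path, body_length: float | None = None) -> MidlineTrack:
    """Read and validate a midline-track CSV.

    ``body_length`` defaults to the time-averaged marker-polyline
    length.  Errors name the offending column or frame.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no frames")
    for col in MIDLINE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    frames = np.sort(df["frame"].unique())
    counts = df.groupby("frame")["marker"].count()
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]].index[0]
        raise ValueError(f"{path}: non-uniform marker count at frame {bad}")
    nm = int(counts.iloc[0])
    xy = np.empty((frames.size, nm, 2))
    times = np.empty(frames.size)
    expect = np.arange(nm)
    for i, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("marker")
        if not np.array_equal(sub["marker"].to_numpy(), expect):
            raise ValueError(f"{path}: gap in marker indices at frame {f}")
        xy[i, :, 0] = sub["x_m"].to_numpy()
        xy[i, :, 1] = sub["y_m"].to_numpy()
        times[i] = sub["time_s"].iloc[0]
    if body_length is None:
        body_length = float(
            np.linalg.norm(np.diff(xy, axis=1), axis=2).sum(axis=1).mean()
        )
    fps = 1.0 / float(np.median(np.diff(times))) if frames.size > 1 else 1.0
    return MidlineTrack(times, xy, body_length, fps)


# ---------------------------------------------------------------------------
# velocity fields


def write_field_sequence(seq: VelocityFieldSequence, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, Y = np.meshgrid(seq.x, seq.y)
    for f in range(seq.n_frames):
        mask = seq.mask[f] if seq.mask is not None else np.zeros_like(X, dtype=bool)
        df = pd.DataFrame({
            "x_m": X.ravel(),
            "y_m": Y.ravel(),
            "u_mps": seq.u[f].ravel(),
            "v_mps": seq.v[f].ravel(),
            "mask": mask.ravel().astype(int),
        })
        df.to_csv(out_dir / f"frame_{f:04d}.csv", index=False)
    meta = {
        "dt_s": seq.dt,
        "U_inf_mps": seq.U_inf,
        "rho_kgpm3": seq.rho,
        "nx": int(seq.x.size),
        "ny": int(seq.y.size),
        "n_frames": int(seq.n_frames),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_field_sequence(in_dir) -> VelocityFieldSequence:
    in_dir = Path(in_dir)
    meta_path = in_dir / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{in_dir}: missing metadata sidecar meta.json")
    meta = json.loads(meta_path.read_text())
    if "dt_s" not in meta:
        raise ValueError(f"{meta_path}: missing dt_s")
    n_frames = int(meta["n_frames"])
    frames = sorted(in_dir.glob("frame_*.csv"))
    found = [int(p.stem.split("_")[1]) for p in frames]
    if found != list(range(n_frames)):
        raise ValueError(f"{in_dir}: non-contiguous frames (found {found})")
    x = y = None
    u = v = mask = None
    for f, path in enumerate(frames):
        df = pd.read_csv(path)
        for col in FIELD_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column '{col}'")
        xf = np.unique(df["x_m"].to_numpy())
        yf = np.unique(df["y_m"].to_numpy())
        if x is None:
            x, y = xf, yf
            shape = (n_frames, y.size, x.size)
            u = np.empty(shape)
            v = np.empty(shape)
            mask = np.zeros(shape, dtype=bool)
        elif xf.size != x.size or yf.size != y.size or not (
                np.allclose(xf, x) and np.allclose(yf, y)):
            raise ValueError(f"{in_dir}: frame {f} grid mismatch")
        order = np.lexsort((df["x_m"].to_numpy(), df["y_m"].to_numpy()))
        u[f] = df["u_mps"].to_numpy()[order].reshape(y.size, x.size)
        v[f] = df["v_mps"].to_numpy()[order].reshape(y.size, x.size)
        mask[f] = df["mask"].to_numpy()[order].reshape(y.size, x.size).astype(bool)
    if not mask.any():
        mask = None
    return VelocityFieldSequence(x, y, u, v, float(meta["dt_s"]),
                                 U_inf=float(meta.get("U_inf_mps", 0.0)),
                                 rho=float(meta.get("rho_kgpm3", 1000.0)),
                                 mask=mask, meta=meta)


def write_field_sequence_h5(seq: VelocityFieldSequence, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("x_m", data=seq.x)
        h5.create_dataset("y_m", data=seq.y)
        h5.create_dataset("u_mps", data=seq.u)
        h5.create_dataset("v_mps", data=seq.v)
        if seq.mask is not None:
            h5.create_dataset("mask", data=seq.mask)
        h5.attrs["dt_s"] = seq.dt
        h5.attrs["U_inf_mps"] = seq.U_inf
        h5.attrs["rho_kgpm3"] = seq.rho
    return path


def load_field_sequence_h5(path) -> VelocityFieldSequence:
    with h5py.File(path, "r") as h5:
        if "dt_s" not in h5.attrs:
            raise ValueError(f"{path}: missing dt_s attribute")
        mask = h5["mask"][:] if "mask" in h5 else None
        return VelocityFieldSequence(
            h5["x_m"][:], h5["y_m"][:], h5["u_mps"][:], h5["v_mps"][:],
            float(h5.attrs["dt_s"]), U_inf=float(h5.attrs.get("U_inf_mps", 0.0)),
            rho=float(h5.attrs.get("rho_kgpm3", 1000.0)), mask=mask,
        )


# ---------------------------------------------------------------------------
# run configuration


_FOIL_KEYS = {"a_sway_m", "a_yaw_deg", "f_hz", "r_te_m", "chord_m", "span_m",
              "U_mps", "nu_m2ps"}
_SWIMMER_KEYS = {"f_hz", "lam_bl", "a_head_m", "a_tail_m", "q", "bl_m",
                 "n_markers", "fps_hz", "noise_sd_m", "heading_rad",
                 "snout_offset_m", "duration_s"}
_WAKE_KEYS = {"gamma_m2ps", "r_c_m", "lam_w_m", "b_m", "U_inf_mps", "U_c_mps",
              "street_sign", "rho_kgpm3", "x_range_m", "y_range_m",
              "spacing_m", "fps_hz", "n_vortices", "duration_s"}
_PRESSURE_KEYS = {"rho_kgpm3", "mu_pas", "time_scheme", "include_viscous",
                  "boundary"}
_TOP_KEYS = {"seed", "out_dir", "foil", "swimmer", "wake", "pressure",
             "follower_distances_m"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (SI units on disk; degrees only in
    human-facing keys carrying a ``_deg`` suffix)."""

    seed: int = 0
    out_dir: str = "thrustwake_out"
    foil: dict = dc_field(default_factory=dict)
    swimmer: dict = dc_field(default_factory=dict)
    wake: dict = dc_field(default_factory=dict)
    pressure: dict = dc_field(default_factory=dict)
    follower_distances_m: list = dc_field(default_factory=lambda: [0.05, 0.12, 0.19, 0.26])


def _reject_unknown(section: str, given: dict, valid: set) -> None:
    unknown = set(given) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in '{section}'; "
            f"valid keys: {sorted(valid)}"
        )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _reject_unknown("top level", raw, _TOP_KEYS)
    _reject_unknown("foil", raw.get("foil", {}), _FOIL_KEYS)
    _reject_unknown("swimmer", raw.get("swimmer", {}), _SWIMMER_KEYS)
    _reject_unknown("wake", raw.get("wake", {}), _WAKE_KEYS)
    _reject_unknown("pressure", raw.get("pressure", {}), _PRESSURE_KEYS)
    return RunConfig(**raw)
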