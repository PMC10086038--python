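"""On-disk containers: HDF5 session/results files, gaze samples, event tables.

Content hashes are computed over dataset names and numerical bytes (not raw
file bytes), so identically seeded runs compare equal regardless of HDF5
header metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .eye_events import GazeRecording
from .layout import SensorLayout
from .simulate import SimSession

__all__ = [
    "save_session", "load_session", "write_gaze_samples", "read_gaze_samples",
    "save_arrays", "load_arrays", "content_hash", "write_events_tsv",
]


def write_gaze_samples(gaze: GazeRecording, path) -> None:
    """Tab-separated samples (time_ms, x_px, y_px), EyeLink-ASC-like dialect."""
    dppx = gaze.units_meta.get("deg_per_px_x", 0.020292)
    dppy = gaze.units_meta.get("deg_per_px_y", 0.020161)
    df = pd.DataFrame({
        "time_ms": np.round(gaze.t * 1000.0, 3),
        "x_px": np.round(gaze.x / dppx + 720.0, 2),
        "y_px": np.round(540.0 - gaze.y / dppy, 2),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_gaze_samples(path, sfreq: float = 1000.0) -> GazeRecording:
    df = pd.read_csv(path, sep="\t")
    dppx, dppy = 0.020292, 0.020161
    return GazeRecording(
        t=df["time_ms"].to_numpy() / 1000.0,
        x=(df["x_px"].to_numpy() - 720.0) * dppx,
        y=(540.0 - df["y_px"].to_numpy()) * dppy,
        sfreq=sfreq,
        units_meta={"deg_per_px_x": dppx, "deg_per_px_y": dppy})


def _df_to_group(df: pd.DataFrame, grp: h5py.Group) -> None:
    for col in df.columns:
        v = df[col].to_numpy()
        if v.dtype == object:
            grp.create_dataset(col, data=np.asarray(v, dtype="S"))
        else:
            grp.create_dataset(col, data=v)
    grp.attrs["columns"] = json.dumps(list(df.columns))


def _df_from_group(grp: h5py.Group) -> pd.DataFrame:
    cols = json.loads(grp.attrs["columns"])
    out = {}
    for col in cols:
        v = grp[col][()]
        if v.dtype.kind == "S":
            v = np.char.decode(v, "utf-8")
        out[col] = v
    return pd.DataFrame(out)


def write_events_tsv(events, path) -> None:
    """Saccade events as a BED-like tab-separated table."""
    rows = [{"onset_s": e.onset_t, "offset_s": e.offset_t,
             "amplitude_deg": e.amplitude, "peak_vel": e.peak_velocity,
             "end_x": e.end_xy[0], "end_y": e.end_xy[1]} for e in events]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def save_session(session: SimSession, outdir) -> Path:
    """Write a session: HDF5 (/meg /photodiode /events /truth), gaze TSV, layout JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h5path = outdir / f"session_p{session.participant:03d}.h5"
    with h5py.File(h5path, "w") as f:
        f.create_dataset("meg", data=session.meg)
        f.create_dataset("photodiode", data=session.photodiode)
        f.attrs["sfreq"] = session.sfreq
        f.attrs["participant"] = session.participant
        f.attrs["ch_names"] = json.dumps(list(session.ch_names))
        _df_to_group(session.events, f.create_group("events"))
        tg = f.create_group("truth")
        tg.create_dataset("theta", data=session.truth["theta"])
        wg = tg.create_group("weights")
        for k, v in session.truth["weights"].items():
            wg.create_dataset(k, data=v)
        tg.attrs["beta_true"] = list(session.truth["beta_true"])
        tg.attrs["residual_amplitude"] = session.truth["residual_amplitude"]
    write_gaze_samples(session.gaze, outdir / f"gaze_p{session.participant:03d}.tsv")
    session.layout.to_json(outdir / "layout.json")
    return h5path


def load_session(outdir, participant: int = 0) -> SimSession:
    outdir = Path(outdir)
    h5path = outdir / f"session_p{participant:03d}.h5"
    layout = SensorLayout.from_json(outdir / "layout.json")
    with h5py.File(h5path, "r") as f:
        meg = f["meg"][()]
        photodiode = f["photodiode"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = json.loads(f.attrs["ch_names"])
        events = _df_from_group(f["events"])
        truth = {
            "theta": f["truth/theta"][()],
            "weights": {k: f["truth/weights"][k][()] for k in f["truth/weights"]},
            "beta_true": tuple(f["truth"].attrs["beta_true"]),
            "residual_amplitude": float(f["truth"].attrs["residual_amplitude"]),
            "kernels": None,
        }
    gaze = read_gaze_samples(outdir / f"gaze_p{participant:03d}.tsv",
                             sfreq=1000.0)
    return SimSession(meg=meg, sfreq=sfreq, ch_names=ch_names, gaze=gaze,
                      photodiode=photodiode, events=events, layout=layout,
                      truth=truth, participant=participant)


def save_arrays(path, arrays: dict, attrs: dict | None = None) -> None:
    """Nested dict of numpy arrays -> HDF5 ('/'-joined keys)."""
    with h5py.File(path, "w") as f:
        def rec(prefix, d):
            for k, v in d.items():
                key = f"{prefix}/{k}" if prefix else str(k)
                if isinstance(v, dict):
                    rec(key, v)
                else:
                    f.create_dataset(key, data=np.asarray(v))
        rec("", arrays)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_arrays(path) -> tuple:
    out = {}
    with h5py.File(path, "r") as f:
        def rec(grp, d):
            for k, v in grp.items():
                if isinstance(v, h5py.Group):
                    d[k] = {}
                    rec(v, d[k])
                else:
                    d[k] = v[()]
        rec(f, out)
        attrs = dict(f.attrs)
    return out, attrs


def content_hash(path) -> str:
    """Stable hash of a file's numerical/text content."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            names = []
            f.visit(names.append)
            for name in sorted(names):
                obj = f[name]
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()
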