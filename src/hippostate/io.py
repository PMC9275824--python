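"""Session container serialization (HDF5) and event-table CSV export."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .csd import ProbeGeometry
from .synth import SessionTruth, SyntheticConfig, SyntheticSession

__all__ = [
    "save_session",
    "load_session",
    "events_to_csv",
    "ripples_to_csv",
    "save_geometry",
    "load_geometry",
    "fir_to_csv",
    "load_landmarks_csv",
    "save_landmarks_csv",
]


def save_session(session: SyntheticSession, path: str) -> None:
    """Write a session to an HDF5 container (groups /lfp, /vm/<cell>, /truth)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        g.create_dataset("data", data=session.lfp, compression="gzip")
        g.attrs["fs"] = session.fs_lfp
        g.attrs["channel_depths_um"] = session.geometry.channel_depths_um
        vm = f.create_group("vm")
        for cid, (subfield, trace) in session.vm.items():
            d = vm.create_dataset(cid, data=trace, compression="gzip")
            d.attrs["subfield"] = subfield
            d.attrs["fs"] = session.fs_vm
        tr = f.create_group("truth")
        tr.create_dataset("epoch_state", data=session.truth.epochs.state.to_numpy())
        tr.create_dataset("epoch_t0", data=session.truth.epochs.t_start_s.to_numpy())
        tr.create_dataset("epoch_t1", data=session.truth.epochs.t_stop_s.to_numpy())
        tr.create_dataset("activity", data=session.truth.activity)
        tr.attrs["fs_activity"] = session.truth.fs_activity
        tr.create_dataset("event_times", data=session.truth.event_times)
        tr.create_dataset("ripple_times", data=session.truth.ripple_times)
        tr.create_dataset("spw_amps", data=session.truth.spw_amps)
        tr.create_dataset("pupil_diameter", data=session.truth.pupil_diameter)
        tr.attrs["fs_pupil"] = session.truth.fs_pupil
        tr.create_dataset("blink_times", data=session.truth.blink_times)
        sp = tr.create_group("spike_times")
        for cid, st in session.truth.spike_times.items():
            sp.create_dataset(cid, data=st)
        tr.attrs["seed"] = session.config.seed
        tr.attrs["duration_s"] = session.config.duration_s


def load_session(path: str) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        lfp = f["lfp/data"][...]
        fs_lfp = float(f["lfp"].attrs["fs"])
        depths = np.asarray(f["lfp"].attrs["channel_depths_um"])
        vm = {}
        fs_vm = None
        for cid in f["vm"]:
            d = f["vm"][cid]
            vm[cid] = (d.attrs["subfield"], d[...])
            fs_vm = float(d.attrs["fs"])
        tr = f["truth"]
        epochs = pd.DataFrame(
            {
                "state": tr["epoch_state"][...],
                "t_start_s": tr["epoch_t0"][...],
                "t_stop_s": tr["epoch_t1"][...],
            }
        )
        truth = SessionTruth(
            epochs=epochs,
            activity=tr["activity"][...],
            fs_activity=float(tr.attrs["fs_activity"]),
            event_times=tr["event_times"][...],
            ripple_times=tr["ripple_times"][...],
            spw_amps=tr["spw_amps"][...],
            spike_times={cid: tr["spike_times"][cid][...] for cid in tr["spike_times"]},
            kernels={},
            templates={},
            pupil_diameter=tr["pupil_diameter"][...],
            fs_pupil=float(tr.attrs["fs_pupil"]),
            blink_times=tr["blink_times"][...],
        )
        cfg = SyntheticConfig(
            seed=int(tr.attrs["seed"]), duration_s=float(tr.attrs["duration_s"])
        )
    geometry = ProbeGeometry(channel_depths_um=depths)
    return SyntheticSession(
        lfp=lfp, fs_lfp=fs_lfp, vm=vm, fs_vm=fs_vm, truth=truth,
        config=cfg, geometry=geometry,
    )


def events_to_csv(times, kinds, path: str, stops=None) -> None:
    """Event table CSV with columns (t_start_s, t_stop_s, kind)."""
    times = np.asarray(times, dtype=float)
    stops = times if stops is None else np.asarray(stops, dtype=float)
    pd.DataFrame({"t_start_s": times, "t_stop_s": stops, "kind": kinds}).to_csv(
        path, index=False
    )


def load_landmarks_csv(path: str) -> list[np.ndarray]:
    """Per-frame pupil landmark sets from a CSV with columns
    (frame, point_id, x, y, likelihood)."""
    df = pd.read_csv(path)
    required = {"frame", "point_id", "x", "y", "likelihood"}
    if not required <= set(df.columns):
        raise ValueError(f"landmark CSV needs columns {sorted(required)}")
    frames = []
    for _, grp in df.sort_values(["frame", "point_id"]).groupby("frame", sort=True):
        frames.append(grp[["x", "y", "likelihood"]].to_numpy(dtype=float))
    return frames


def save_landmarks_csv(frames: list[np.ndarray], path: str) -> None:
    rows = [
        (i, j, *pt)
        for i, fr in enumerate(frames)
        for j, pt in enumerate(np.asarray(fr, dtype=float))
    ]
    pd.DataFrame(
        rows, columns=["frame", "point_id", "x", "y", "likelihood"]
    ).to_csv(path, index=False)


def save_geometry(geometry: ProbeGeometry, path: str) -> None:
    """Probe-geometry sidecar (JSON: depth_um per channel, bad_channels)."""
    import json

    with open(path, "w") as f:
        json.dump(
            {
                "depth_um": geometry.channel_depths_um.tolist(),
                "bad_channels": sorted(geometry.bad_channels),
                "conductivity": geometry.conductivity,
                "source_diameter_um": geometry.source_diameter_um,
            },
            f,
            indent=2,
        )


def load_geometry(path: str) -> ProbeGeometry:
    import json

    with open(path) as f:
        d = json.load(f)
    return ProbeGeometry(
        channel_depths_um=np.asarray(d["depth_um"], dtype=float),
        bad_channels=frozenset(d.get("bad_channels", ())),
        conductivity=d.get("conductivity", 0.3),
        source_diameter_um=d.get("source_diameter_um", 500.0),
    )


def fir_to_csv(result, csv_path: str, json_path: str | None = None) -> None:
    """Fitted FIR filter as (lag_s, coefficient) CSV + JSON hyperparameters."""
    import json

    pd.DataFrame(
        {"lag_s": result.lags_s, "coefficient": result.coefficients}
    ).to_csv(csv_path, index=False)
    if json_path:
        with open(json_path, "w") as f:
            json.dump(
                {
                    **{k: float(v) for k, v in result.hyperparameters.items()},
                    "rsquared": result.rsquared,
                    "fs_model": result.fs_model,
                    "n_obs": result.n_obs,
                },
                f,
                indent=2,
            )


def ripples_to_csv(events, path: str) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "peak_power_z": ev.peak_power_z,
                "spw_amplitude": ev.spw_amplitude,
                "size_class": ev.size_class,
                "isolation": ev.isolation,
            }
            for ev in events
        ]
    ).to_csv(path, index=False)
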