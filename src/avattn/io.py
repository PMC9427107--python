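"""Session container I/O and configuration.

Sessions round-trip through HDF5 with groups ``/units`` (per-unit spike
times and metadata), ``/trials`` (columnar trial table), ``/rds`` (per-epoch
sweep trajectories), and ``/channels`` (laminar profile); the trial table
also exports to flat CSV.  Configuration is YAML mapped onto
:class:`avattn.session.SessionConfig`, with seeds echoed into the output
metadata for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from io import StringIO

import h5py
import numpy as np
import pandas as pd
import yaml

from .session import ChannelProfile, RDSEpoch, SessionConfig, SessionData
from .stimuli import RDSStimulus

_TRIAL_STR_COLS = ("rule", "modality", "stimulus", "outcome")


def load_config(path) -> SessionConfig:
    """Read a YAML config, overlaying defaults; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("hit_rate", "fa_rate", "a_rule_factor_by_group"):
        if key in raw and not isinstance(raw[key], dict):
            raise ValueError(f"config key {key} must be a mapping")
    if "unit_counts" in raw:
        raw["unit_counts"] = {
            tuple(k.split("/")): v for k, v in raw["unit_counts"].items()
        }
    for key in ("iti_range_s", "depth_boundaries"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SessionConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(config: SessionConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["unit_counts"] = {"/".join(k): v for k, v in d["unit_counts"].items()}
    d["iti_range_s"] = list(d["iti_range_s"])
    d["depth_boundaries"] = list(d["depth_boundaries"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def write_session(data: SessionData, path) -> None:
    """Write a session container to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["meta_json"] = json.dumps(data.meta)
        gu = f.create_group("units")
        for i, st in enumerate(data.spike_times):
            gu.create_dataset(f"{i:04d}/spike_times", data=np.asarray(st))
        gu.attrs["table_json"] = data.unit_table.to_json(orient="split")
        gt = f.create_group("trials")
        gt.attrs["columns"] = list(data.trials.columns)
        for col in data.trials.columns:
            vals = data.trials[col].to_numpy()
            if col in _TRIAL_STR_COLS:
                gt.create_dataset(col, data=vals.astype("S"))
            else:
                gt.create_dataset(col, data=vals)
        gr = f.create_group("rds")
        for k, ep in enumerate(data.rds_epochs):
            g = gr.create_group(f"{k:04d}")
            g.create_dataset("sweep_tracks", data=ep.stimulus.sweep_tracks)
            g.attrs.update(
                start=ep.start,
                stop=ep.stop,
                rule=ep.rule,
                block=ep.block,
                dt_traj=ep.stimulus.dt_traj,
                seed=ep.stimulus.seed,
            )
        gc = f.create_group("channels")
        gc.create_dataset("lfp_amp", data=data.channel_profile.lfp_amp)
        gc.create_dataset("mua_responsive", data=data.channel_profile.mua_responsive)


def read_session(path) -> SessionData:
    """Read a session container from HDF5."""
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta_json"])
        gu = f["units"]
        spike_times = [gu[k]["spike_times"][()] for k in sorted(gu.keys())]
        unit_table = pd.read_json(StringIO(gu.attrs["table_json"]), orient="split")
        gt = f["trials"]
        order = list(gt.attrs["columns"])
        cols = {}
        for col in order:
            v = gt[col][()]
            cols[col] = v.astype(str) if col in _TRIAL_STR_COLS else v
        trials = pd.DataFrame(cols).sort_values("trial").reset_index(drop=True)
        epochs = []
        gr = f["rds"]
        for k in sorted(gr.keys()):
            g = gr[k]
            tracks = g["sweep_tracks"][()]
            stim = RDSStimulus(
                sweep_tracks=tracks,
                dt_traj=float(g.attrs["dt_traj"]),
                duration=tracks.shape[1] * float(g.attrs["dt_traj"]),
                seed=int(g.attrs["seed"]),
            )
            epochs.append(
                RDSEpoch(
                    start=float(g.attrs["start"]),
                    stop=float(g.attrs["stop"]),
                    rule=str(g.attrs["rule"]),
                    block=int(g.attrs["block"]),
                    stimulus=stim,
                )
            )
        channels = ChannelProfile(
            lfp_amp=f["channels"]["lfp_amp"][()],
            mua_responsive=f["channels"]["mua_responsive"][()].astype(bool),
        )
    return SessionData(
        spike_times=spike_times,
        unit_table=unit_table,
        trials=trials,
        rds_epochs=epochs,
        channel_profile=channels,
        meta=meta,
    )


def export_trials_csv(data: SessionData, path) -> None:
    data.trials.to_csv(path, index=False)


def import_external_session(path):  # pragma: no cover - adapter stub
    """Adapter for mapping an externally deposited dataset into the session
    container.  Declared interface only; external data are not required for
    any analysis in this package."""
    raise NotImplementedError(
        "external dataset import is a declared interface without an implementation"
    )
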