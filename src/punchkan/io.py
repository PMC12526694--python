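"""Dataset persistence and configuration.

HDF5 layout (schema version 1):

    /                      attrs: schema_version, seed, fs, punch_count
    /subjects              table-like datasets: subject_id, body_mass,
                           subject_effect, emg_gain
    /records/{rid}/emg     (T, C) float32, attrs: fs, stage, channel_labels
    /records/{rid}/force   (T,)  float32, attrs: fs
    /records/{rid}         attrs: subject_id, condition, punch_index,
                           punch-pulse anchors (f_peak, f5ms, t50, t90,
                           t_peak, decay_tau, contact_time, punch_type)

A CSV manifest (one row per record: subject_id, condition, punch_index,
record path) is written next to the HDF5 file. YAML configs mirror the
CohortConfig / ConditionSpec / CouplingSpec fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortConfig,
    CohortDataset,
    CohortRecord,
    ConditionSpec,
    CouplingSpec,
    PunchPulseParams,
    SubjectProfile,
)
from .kinetics import ForceTrace
from .preprocessing import EMGTrace

SCHEMA_VERSION = 1

__all__ = [
    "write_dataset",
    "read_dataset",
    "manifest_path",
    "load_config",
    "dump_config",
    "default_config_dict",
]


class SchemaError(RuntimeError):
    pass


def manifest_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".manifest.csv") if p.suffix else p.with_suffix(".manifest.csv")


def _record_id(sid: str, cond: str, punch: int) -> str:
    return f"{sid}_{cond}_{punch:03d}"


def write_dataset(ds: CohortDataset, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["seed"] = ds.seed
        f.attrs["fs"] = ds.config.fs
        f.attrs["punch_count_per_session"] = ds.punch_count_per_session
        f.attrs["config_json"] = json.dumps(config_to_dict(ds.config))
        g = f.create_group("subjects")
        g.create_dataset("subject_id", data=[s.subject_id for s in ds.subjects])
        g.create_dataset("body_mass", data=[s.body_mass for s in ds.subjects])
        g.create_dataset("subject_effect", data=[s.subject_effect for s in ds.subjects])
        g.create_dataset("emg_gain", data=[s.emg_gain for s in ds.subjects])
        recs = f.create_group("records")
        manifest = []
        for (sid, cond, pi), rec in ds.records.items():
            rid = _record_id(sid, cond, pi)
            rg = recs.create_group(rid)
            rg.attrs.update(
                subject_id=sid, condition=cond, punch_index=pi,
                **{k: getattr(rec.params_true, k) for k in (
                    "f_peak", "f5ms", "t50", "t90", "t_peak",
                    "decay_tau", "contact_time", "punch_type",
                )},
            )
            d = rg.create_dataset("emg", data=rec.emg.samples.astype(np.float32))
            d.attrs["fs"] = rec.emg.fs
            d.attrs["stage"] = rec.emg.stage
            d.attrs["channel_labels"] = list(rec.emg.channel_labels)
            d = rg.create_dataset("force", data=rec.force.samples.astype(np.float32))
            d.attrs["fs"] = rec.force.fs
            manifest.append((sid, cond, pi, f"records/{rid}"))
    pd.DataFrame(
        manifest, columns=["subject_id", "condition", "punch_index", "record_path"]
    ).to_csv(manifest_path(path), index=False)


def read_dataset(path) -> CohortDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise SchemaError("missing fs attribute; not a cohort dataset")
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {f.attrs.get('schema_version')!r} != {SCHEMA_VERSION}"
            )
        config = config_from_dict(json.loads(f.attrs["config_json"]))
        g = f["subjects"]
        subjects = [
            SubjectProfile(
                sid.decode() if isinstance(sid, bytes) else str(sid),
                float(m), float(e), float(gn),
            )
            for sid, m, e, gn in zip(
                g["subject_id"][()], g["body_mass"][()],
                g["subject_effect"][()], g["emg_gain"][()],
            )
        ]
        records: Dict[tuple, CohortRecord] = {}
        for rid, rg in f["records"].items():
            a = rg.attrs
            params = PunchPulseParams(
                f_peak=float(a["f_peak"]), f5ms=float(a["f5ms"]),
                t50=float(a["t50"]), t90=float(a["t90"]), t_peak=float(a["t_peak"]),
                decay_tau=float(a["decay_tau"]), contact_time=float(a["contact_time"]),
                punch_type=str(a["punch_type"]),
            )
            emg_ds = rg["emg"]
            emg = EMGTrace(
                emg_ds[()].astype(np.float64),
                float(emg_ds.attrs["fs"]),
                tuple(
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in emg_ds.attrs["channel_labels"]
                ),
                str(emg_ds.attrs["stage"]),
            )
            force = ForceTrace(rg["force"][()].astype(np.float64), float(rg["force"].attrs["fs"]))
            key = (str(a["subject_id"]), str(a["condition"]), int(a["punch_index"]))
            records[key] = CohortRecord(emg, force, params)
        frame = pd.DataFrame(
            [
                {"subject_id": k[0], "condition": k[1], "punch_index": k[2]}
                for k in records
            ]
        )
        return CohortDataset(
            subjects=subjects,
            records=records,
            seed=int(f.attrs["seed"]),
            punch_count_per_session=int(f.attrs["punch_count_per_session"]),
            config=config,
            params_frame=frame,
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["conditions"] = {
        name: dataclasses.asdict(spec) for name, spec in config.conditions.items()
    }
    d["coupling"] = dataclasses.asdict(config.coupling)
    for key in ("punch_type_mix", "punch_type_scale", "mass_bounds"):
        d[key] = [list(t) for t in d[key]] if key != "mass_bounds" else list(d[key])
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "conditions" in d:
        d["conditions"] = {
            name: ConditionSpec(**spec) for name, spec in d["conditions"].items()
        }
    if "coupling" in d:
        cp = dict(d["coupling"])
        cp["channel_weights"] = tuple(cp.get("channel_weights", ()))
        d["coupling"] = CouplingSpec(**cp)
    for key in ("punch_type_mix", "punch_type_scale"):
        if key in d:
            d[key] = tuple((str(a), float(b)) for a, b in d[key])
    if "mass_bounds" in d:
        d["mass_bounds"] = tuple(d["mass_bounds"])
    return CohortConfig(**d)


def default_config_dict() -> dict:
    return config_to_dict(CohortConfig())


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base = default_config_dict()
    use = data.pop("use_conditions", None)  # optional subset of condition names
    for k, v in data.items():
        if k == "conditions":
            for name, spec in v.items():
                base["conditions"].setdefault(name, {}).update(spec)
        elif k == "coupling":
            base["coupling"].update(v)
        else:
            base[k] = v
    if use:
        base["conditions"] = {n: base["conditions"][n] for n in use}
    return config_from_dict(base)


def dump_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
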