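"""CSV/YAML data formats and reproducibility plumbing.

Formats (all plain text):

* receivers:  ``receiver_id,x,y``
* detections: ``tag_id,receiver_id,time``  (one row per logged detection)
* truth:      ``tag_id,signal_index,time,x,y`` (simulation output only)
* config:     YAML mirroring :class:`~mvlocate.simulate.SimConfig` fields
* draws:      long CSV ``chain,iter,param,value``

Real receivers log (tag, receiver, time) rows independently; detections of
one signal arriving at several receivers are grouped into a single encounter
vector when their times fall within a binning tolerance of the first
detection in the group (default ``a / 2`` when the minimum signal interval
``a`` is known, else 1.0 time unit).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._mh import TagData
from .kernels import DetectionParams, MovementParams, ReceiverArray
from .simulate import SimConfig, SimulatedDataset

__all__ = [
    "read_receivers",
    "write_receivers",
    "read_detections",
    "write_detections",
    "detections_to_tagdata",
    "write_truth",
    "read_truth",
    "read_config",
    "write_config",
    "write_param_draws",
    "write_manifest",
]


def read_receivers(path) -> ReceiverArray:
    df = pd.read_csv(path)
    required = ["receiver_id", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {required}")
    for col in ("x", "y"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} at rows {list(bad.index + 2)}")
    return ReceiverArray(
        ids=tuple(df["receiver_id"].tolist()),
        coords=df[["x", "y"]].to_numpy(dtype=float),
    )


def write_receivers(array: ReceiverArray, path) -> None:
    pd.DataFrame(
        {"receiver_id": list(array.ids), "x": array.coords[:, 0], "y": array.coords[:, 1]}
    ).to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["tag_id", "receiver_id", "time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {required}")
    bad = df[pd.to_numeric(df["time"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric 'time' at rows {list(bad.index + 2)}")
    df = df.sort_values(["tag_id", "time"], kind="mergesort").reset_index(drop=True)
    return df


def write_detections(dataset: SimulatedDataset, path) -> None:
    rows = []
    for tag in dataset.tags:
        t_idx, r_idx = np.nonzero(tag.encounters)
        for ti, ri in zip(t_idx, r_idx):
            rows.append((tag.tag_id, dataset.array.ids[ri], tag.schedule.times[ti]))
    pd.DataFrame(rows, columns=["tag_id", "receiver_id", "time"]).to_csv(path, index=False)


def detections_to_tagdata(df: pd.DataFrame, array: ReceiverArray,
                          tolerance: float = 1.0) -> list[TagData]:
    """Group logged detections into per-signal encounter vectors.

    Detections of a tag within ``tolerance`` of the first detection of the
    current group are treated as one signal; the group's time stamp is that
    first detection time.
    """
    id_to_col = {rid: j for j, rid in enumerate(array.ids)}
    unknown = set(df["receiver_id"]) - set(array.ids)
    if unknown:
        raise ValueError(f"unknown receiver_id values: {sorted(unknown)!r}")
    out = []
    for tag_id, sub in df.groupby("tag_id", sort=True):
        times, rows = [], []
        cur_t0 = None
        cur = None
        for _, rec in sub.iterrows():
            t = float(rec["time"])
            if cur_t0 is None or t - cur_t0 > tolerance:
                if cur is not None:
                    rows.append(cur)
                    times.append(cur_t0)
                cur_t0 = t
                cur = np.zeros(array.n_receivers, dtype=np.uint8)
            cur[id_to_col[rec["receiver_id"]]] = 1
        if cur is not None:
            rows.append(cur)
            times.append(cur_t0)
        out.append(TagData(tag_id=tag_id, times=np.array(times), Y=np.array(rows)))
    return out


def write_truth(dataset: SimulatedDataset, path) -> None:
    rows = []
    for tag in dataset.tags:
        for i, (t, u) in enumerate(zip(tag.schedule.times, tag.trajectory)):
            rows.append((tag.tag_id, i, t, u[0], u[1]))
    pd.DataFrame(rows, columns=["tag_id", "signal_index", "time", "x", "y"]).to_csv(
        path, index=False
    )


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["tag_id", "signal_index", "time", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.sort_values(["tag_id", "signal_index"]).reset_index(drop=True)


def _config_to_dict(config: SimConfig) -> dict:
    det = config.det
    return {
        "n_individuals": config.n_individuals,
        "grid_nx": config.grid_nx,
        "grid_ny": config.grid_ny,
        "spacing": config.spacing,
        "a": config.a,
        "b": config.b,
        "duration": config.duration,
        "det": {
            "family": det.family,
            **{k: getattr(det, k) for k in ("p0", "sigma_det", "alpha0", "alpha1", "theta")
               if getattr(det, k) is not None},
        },
        "move": {"sigma_u": config.move.sigma_u},
        "buffer_mult": config.buffer_mult,
        "seed": config.seed,
    }


def write_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))


def read_config(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    det = DetectionParams(**raw.pop("det")) if "det" in raw else None
    move = MovementParams(**raw.pop("move")) if "move" in raw else None
    kwargs = dict(raw)
    if det is not None:
        kwargs["det"] = det
    if move is not None:
        kwargs["move"] = move
    return SimConfig(**kwargs)


def write_param_draws(params: dict, path) -> None:
    """Long-format CSV of posterior parameter draws: chain,iter,param,value."""
    rows = []
    for name, arr in params.items():
        arr = np.asarray(arr)
        for c in range(arr.shape[0]):
            for i, v in enumerate(arr[c]):
                rows.append((c, i, name, v))
    pd.DataFrame(rows, columns=["chain", "iter", "param", "value"]).to_csv(path, index=False)


def write_manifest(out_dir, config_dict: dict, seed, input_paths=()) -> None:
    """YAML manifest: config, seed, and content hashes of the inputs, enough
    to reproduce deterministic stages bit-for-bit."""
    hashes = {}
    for p in input_paths:
        p = Path(p)
        hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config": config_dict, "seed": seed, "input_sha256": hashes}
    Path(out_dir, "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
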