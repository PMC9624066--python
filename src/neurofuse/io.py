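"""File formats: HDF5 epoch/pattern containers, CSV RDMs, TSV tables.

HDF5 epoch layout (schema 1.0): datasets ``/data`` (trial x channel x time,
float32), ``/time_ms``, ``/labels`` (compound: condition_id, category,
identity, variation, repetition, run; run -1 when absent), ``/channels``
(compound: name, region, source_participant); root attributes ``sfreq``,
``participant_id``, ``modality``, ``schema_version``. Round trips are
lossless for labels and metadata and within float32 rounding for data.

RDMs are CSV with a condition-id header row, NaN on the diagonal; symmetry
is validated on read (tolerance 1e-9).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .generator import EpochedRecording, PatternSet
from .rsa import RDM

SCHEMA_VERSION = "1.0"

_STR = h5py.string_dtype(encoding="utf-8")


def _labels_to_records(labels: pd.DataFrame) -> np.ndarray:
    dt = np.dtype(
        [
            ("condition_id", "i8"),
            ("category", _STR),
            ("identity", "i8"),
            ("variation", _STR),
            ("repetition", "i8"),
            ("run", "i8"),
        ]
    )
    rec = np.empty(len(labels), dtype=dt)
    rec["condition_id"] = labels["condition_id"].to_numpy()
    rec["category"] = labels["category"].astype(str).to_numpy()
    rec["identity"] = labels["identity"].to_numpy()
    rec["variation"] = labels["variation"].astype(str).to_numpy()
    rec["repetition"] = labels["repetition"].to_numpy()
    run = labels["run"] if "run" in labels.columns else pd.Series([pd.NA] * len(labels))
    rec["run"] = run.fillna(-1).to_numpy(dtype="i8")
    return rec


def _records_to_labels(rec: np.ndarray) -> pd.DataFrame:
    def dec(col):
        return [v.decode() if isinstance(v, bytes) else str(v) for v in rec[col]]

    df = pd.DataFrame(
        {
            "condition_id": rec["condition_id"].astype(int),
            "category": dec("category"),
            "identity": rec["identity"].astype(int),
            "variation": dec("variation"),
            "repetition": rec["repetition"].astype(int),
            "run": rec["run"].astype(int),
        }
    )
    df["run"] = df["run"].mask(df["run"] < 0).astype("Int64")
    return df


def write_epochs(path: str | Path, rec: EpochedRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("time_ms", data=rec.time_ms)
        f.create_dataset("labels", data=_labels_to_records(rec.labels))
        ch_dt = np.dtype([("name", _STR), ("region", _STR), ("source_participant", _STR)])
        ch = np.empty(len(rec.channels), dtype=ch_dt)
        ch["name"] = rec.channels["name"].astype(str).to_numpy()
        ch["region"] = rec.channels["region"].fillna("").astype(str).to_numpy()
        ch["source_participant"] = (
            rec.channels["source_participant"].fillna("").astype(str).to_numpy()
        )
        f.create_dataset("channels", data=ch)
        if "selective" in rec.channels.columns:
            f.create_dataset("selective", data=rec.channels["selective"].to_numpy(bool))
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["participant_id"] = rec.participant_id
        f.attrs["modality"] = rec.modality
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_epochs(path: str | Path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"schema_version mismatch: file has {version!r}, expected {SCHEMA_VERSION!r}"
            )
        for ds in ("data", "time_ms", "labels", "channels"):
            if ds not in f:
                raise ValueError(f"missing dataset '/{ds}' in {path}")
        data = f["data"][()].astype(np.float64)
        time_ms = f["time_ms"][()]
        labels = _records_to_labels(f["labels"][()])
        chrec = f["channels"][()]

        def dec(col):
            return [v.decode() if isinstance(v, bytes) else str(v) for v in chrec[col]]

        channels = pd.DataFrame(
            {
                "name": dec("name"),
                "region": pd.array(
                    [r if r else pd.NA for r in dec("region")], dtype="string"
                ),
                "source_participant": pd.array(
                    [s if s else pd.NA for s in dec("source_participant")], dtype="string"
                ),
            }
        )
        if "selective" in f:
            channels["selective"] = f["selective"][()].astype(bool)
        if data.shape[0] != len(labels):
            raise ValueError(
                f"shape mismatch: {data.shape[0]} trials but {len(labels)} label rows"
            )
        if data.shape[1] != len(channels):
            raise ValueError(
                f"shape mismatch: {data.shape[1]} channels but {len(channels)} channel rows"
            )
        return EpochedRecording(
            data,
            time_ms,
            float(f.attrs["sfreq"]),
            channels,
            str(f.attrs["participant_id"]),
            str(f.attrs["modality"]),
            labels,
        )


def write_patterns(path: str | Path, ps: PatternSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("betas", data=ps.betas.astype(np.float32))
        f.create_dataset("labels", data=_labels_to_records(ps.labels))
        f.attrs["roi"] = ps.roi
        f.attrs["participant_id"] = ps.participant_id
        f.attrs["run"] = -1 if ps.run is None else int(ps.run)
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_patterns(path: str | Path) -> PatternSet:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"schema_version mismatch: file has {version!r}, expected {SCHEMA_VERSION!r}"
            )
        for ds in ("betas", "labels"):
            if ds not in f:
                raise ValueError(f"missing dataset '/{ds}' in {path}")
        run = int(f.attrs["run"])
        return PatternSet(
            f["betas"][()].astype(np.float64),
            _records_to_labels(f["labels"][()]),
            roi=str(f.attrs["roi"]),
            participant_id=str(f.attrs["participant_id"]),
            run=None if run < 0 else run,
        )


def write_rdm(path: str | Path, rdm: RDM) -> None:
    df = pd.DataFrame(
        rdm.values, index=rdm.condition_order, columns=rdm.condition_order
    )
    df.to_csv(path, index_label="condition_id")


def read_rdm(path: str | Path) -> RDM:
    df = pd.read_csv(path, index_col="condition_id")
    values = df.to_numpy(dtype=float)
    asym = np.nanmax(np.abs(values - values.T)) if values.size else 0.0
    if asym > 1e-9:
        raise ValueError(f"RDM in {path} asymmetric by {asym}")
    values = 0.5 * (values + values.T)
    order = df.index.to_numpy()
    return RDM(values, order)


def write_rdm_series(directory: str | Path, rdms: list[RDM], stem: str = "rdm") -> list[Path]:
    """Write a time-resolved RDM set as one CSV per timepoint.

    Files are named ``<stem>_t<index>.csv`` in sample order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rdm in enumerate(rdms):
        p = directory / f"{stem}_t{i:04d}.csv"
        write_rdm(p, rdm)
        paths.append(p)
    return paths


def write_rdm_stack(path: str | Path, rdms: list[RDM], time_ms=None) -> None:
    """Write a time-resolved RDM set as one HDF5 stack.

    Layout: ``/values`` (time x condition x condition, NaN diagonal),
    ``/condition_order``, optional ``/time_ms``; ``schema_version`` attr.
    """
    order = rdms[0].condition_order
    for r in rdms[1:]:
        if not np.array_equal(r.condition_order, order):
            raise ValueError("condition orders differ within the stack")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.stack([r.values for r in rdms]))
        f.create_dataset("condition_order", data=np.asarray(order, dtype="i8"))
        if time_ms is not None:
            f.create_dataset("time_ms", data=np.asarray(time_ms, dtype=float))
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_rdm_stack(path: str | Path) -> tuple[list[RDM], np.ndarray | None]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("schema_version mismatch")
        values = f["values"][()]
        order = f["condition_order"][()]
        time_ms = f["time_ms"][()] if "time_ms" in f else None
    rdms = [RDM(v, order) for v in values]
    if time_ms is not None:
        for r, t in zip(rdms, time_ms):
            r.meta["time_ms"] = float(t)
    return rdms, time_ms


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """TSV writer used for decoding results, stats and fusion outputs."""
    df.to_csv(path, sep="\t", index=False)


def digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_provenance(path: str | Path, **fields) -> None:
    """JSON sidecar: parameters, seeds and input digests for reproduction."""
    Path(path).write_text(json.dumps(_jsonable(fields), indent=2, sort_keys=True))
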