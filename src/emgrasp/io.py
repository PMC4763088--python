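"""Recording and model serialisation.

Canonical on-disk recording format is columnar text: ``#``-prefixed header
lines carrying the sample rate, channel roles and wrist condition, followed
by a CSV body with ``time_ms``, one column per channel (``ch01``...), and a
``label`` column.  An HDF5 container (same fields as datasets/attributes) is
supported for bulk datasets.  Round-trips are lossless for values and
metadata.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .lda import LdaModel
from .recording import SAMPLE_RATE_HZ, EmgRecording
from .synth import parse_wrist_tag


def _channel_names(n: int) -> list[str]:
    return [f"ch{i + 1:02d}" for i in range(n)]


def write_recording(recording: EmgRecording, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_h5(recording, path)
        return
    cols = _channel_names(recording.n_channels)
    df = pd.DataFrame(np.asarray(recording.samples, dtype=float), columns=cols)
    df.insert(0, "time_ms", np.arange(recording.n_samples))
    df["label"] = recording.labels
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {recording.sample_rate_hz}\n")
        fh.write(f"# channel_roles: {','.join(recording.channel_roles)}\n")
        fh.write(f"# wrist_condition: {recording.wrist_condition}\n")
        fh.write(f"# meta: {json.dumps(recording.meta)}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_recording(path) -> EmgRecording:
    """Read a recording, validating header consistency.

    Raises
    ------
    ValueError
        On missing header fields, a sample rate other than 1000 Hz, a
        channel-role count that disagrees with the data columns, or an
        unknown wrist-condition tag (valid tags are listed).
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    header: dict[str, str] = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    return _build_recording(header, pd.read_csv(body))


def _build_recording(header: dict, df: pd.DataFrame) -> EmgRecording:
    missing = {"sample_rate_hz", "channel_roles", "wrist_condition"} - set(header)
    if missing:
        raise ValueError(f"recording header is missing field(s): {sorted(missing)}")
    rate = int(float(header["sample_rate_hz"]))
    if rate != SAMPLE_RATE_HZ:
        raise ValueError(f"unsupported sample rate {rate} Hz; recordings must be {SAMPLE_RATE_HZ} Hz")
    roles = tuple(r.strip() for r in header["channel_roles"].split(","))
    tag = header["wrist_condition"]
    parse_wrist_tag(tag)  # raises with the list of valid tags
    ch_cols = [c for c in df.columns if c.startswith("ch")]
    if len(roles) != len(ch_cols):
        raise ValueError(
            f"header declares {len(roles)} channel roles but the file has "
            f"{len(ch_cols)} channel columns"
        )
    meta = json.loads(header.get("meta", "{}"))
    return EmgRecording(
        samples=df[ch_cols].to_numpy(dtype=np.float32),
        channel_roles=roles,
        labels=df["label"].to_numpy(dtype=object),
        wrist_condition=tag,
        sample_rate_hz=rate,
        meta=meta,
    )


def _write_h5(recording: EmgRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.asarray(recording.samples, dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(recording.labels, dtype="S32"))
        f.attrs["sample_rate_hz"] = recording.sample_rate_hz
        f.attrs["channel_roles"] = ",".join(recording.channel_roles)
        f.attrs["wrist_condition"] = recording.wrist_condition
        f.attrs["meta"] = json.dumps(recording.meta)


def _read_h5(path: Path) -> EmgRecording:
    with h5py.File(path, "r") as f:
        header = {k: str(f.attrs[k]) for k in f.attrs}
        samples = f["samples"][()]
        labels = f["labels"][()].astype(str)
    df = pd.DataFrame(samples, columns=_channel_names(samples.shape[1]))
    df["label"] = labels
    return _build_recording(header, df)


def write_dataset(recordings, directory, fmt: str = "csv") -> pd.DataFrame:
    """Write a list of recordings plus a manifest CSV; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        cls = rec.meta.get("class", "unknown")
        rep = rec.meta.get("rep", 0)
        wrist = rec.wrist_condition.replace(":", "_").replace("-", "_")
        name = f"{i:04d}_{cls}_{wrist}_r{rep}.{ 'h5' if fmt == 'h5' else 'csv'}"
        write_recording(rec, directory / name)
        rows.append({"file": name, "class": cls, "wrist_condition": rec.wrist_condition,
                     "rep": rep, "duration_ms": rec.duration_ms})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_dataset(directory) -> list[EmgRecording]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [read_recording(directory / name) for name in manifest["file"]]


# ---------------------------------------------------------------------------
# Models and configuration


def save_model(model: LdaModel, path) -> None:
    np.savez(
        path,
        classes=np.asarray(model.classes, dtype="U32"),
        means=model.means,
        covariance=model.covariance,
        priors=model.priors,
        shrinkage=model.shrinkage,
    )


def load_model(path) -> LdaModel:
    data = np.load(path, allow_pickle=False)
    return LdaModel(
        classes=tuple(data["classes"].tolist()),
        means=data["means"],
        covariance=data["covariance"],
        priors=data["priors"],
        shrinkage=float(data["shrinkage"]),
    )


def load_config(path) -> dict:
    """YAML run configuration as a plain mapping (missing file -> error)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg
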