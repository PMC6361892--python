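"""File formats: recordings, annotations, connectivity matrices, edge masks.

Recordings travel as a delimited numeric matrix (samples x channels, CSV with
channel labels as the header row) plus a JSON sidecar carrying the sampling
rate, or as EDF (read-only, via MNE).  Annotations are CSV with columns
``start_s, end_s, kind, condition``.  Connectivity matrices are CSV with the
channel labels as header row and index column and a JSON sidecar holding the
band and epoch count; edge masks are CSV edge lists ``label_a, label_b``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Annotation, Recording
from .spectral import ConnectivityMatrix, EdgeMask

__all__ = [
    "write_recording",
    "read_recording",
    "write_annotations",
    "read_annotations",
    "write_connectivity",
    "read_connectivity",
    "write_edge_mask",
    "read_edge_mask",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write samples as CSV (samples x channels) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    df.to_csv(path, index=False, float_format="%.6g")
    meta = {"fs": recording.fs, "channel_labels": recording.channel_labels, "unit": "uV"}
    _sidecar_path(path).write_text(json.dumps(meta))


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from EDF or delimited matrix + JSON sidecar.

    ``fmt`` is inferred from the extension when None (``.edf`` vs anything
    else).  EDF data are converted to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            samples=raw.get_data() * 1e6,  # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            annotations=[],
        )
    if fmt == "csv":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"delimited recording {path} has no JSON sidecar {sidecar}"
            )
        meta = json.loads(sidecar.read_text())
        df = pd.read_csv(path)
        labels = meta.get("channel_labels", list(df.columns))
        if list(df.columns) != list(labels):
            raise ValueError(
                f"channel labels in {path} header do not match sidecar: "
                f"{list(df.columns)} vs {labels}"
            )
        return Recording(
            samples=df.to_numpy(dtype=float).T,
            fs=float(meta["fs"]),
            channel_labels=list(labels),
            annotations=[],
        )
    raise ValueError(f"unknown recording format '{fmt}'")


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"start_s": a.start, "end_s": a.end, "kind": a.kind, "condition": a.condition}
            for a in annotations
        ],
        columns=["start_s", "end_s", "kind", "condition"],
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file {path} must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        cond = row.get("condition", "")
        out.append(
            Annotation(
                start=float(row["start_s"]),
                end=float(row["end_s"]),
                kind=str(row["kind"]),
                condition="" if pd.isna(cond) else str(cond),
            )
        )
    return out


def write_connectivity(m: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    labels = m.channel_labels or [f"ch{i:03d}" for i in range(m.n_channels)]
    pd.DataFrame(m.values, index=labels, columns=labels).to_csv(path, float_format="%.10g")
    meta = {"band": list(m.band), "n_epochs": m.n_epochs}
    _sidecar_path(path).write_text(json.dumps(meta))


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(_sidecar_path(path).read_text())
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float),
        band=tuple(meta["band"]),
        n_epochs=int(meta["n_epochs"]),
        channel_labels=list(df.columns),
    )


def write_edge_mask(mask: EdgeMask, path: str | Path) -> None:
    labels = mask.channel_labels or [f"ch{i:03d}" for i in range(mask.mask.shape[0])]
    rows = [{"label_a": labels[i], "label_b": labels[j]} for i, j in mask.edges()]
    pd.DataFrame(rows, columns=["label_a", "label_b"]).to_csv(path, index=False)


def read_edge_mask(path: str | Path, channel_labels: list[str]) -> EdgeMask:
    df = pd.read_csv(path)
    index = {lab: k for k, lab in enumerate(channel_labels)}
    edges = []
    for _, row in df.iterrows():
        a, b = str(row["label_a"]), str(row["label_b"])
        if a not in index or b not in index:
            raise ValueError(f"edge mask references unknown channel: {a} or {b}")
        edges.append((index[a], index[b]))
    return EdgeMask.from_edges(edges, len(channel_labels), list(channel_labels))
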