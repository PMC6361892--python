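"""End-to-end orchestration: epoching -> dbWPLI -> NBS -> cohort statistics.

`analyze_cohort` is the in-memory engine; `run_pipeline` wraps it with file
I/O driven by a YAML/JSON configuration (per-subject recording and annotation
paths in a cohort table, preprocessing parameters, frequency band, optional
selected-connection edge mask, group comparisons, correlation families).
Every stochastic stage derives its seed from the single pipeline seed, so a
re-run with the same config and inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .cohort import TestResult, choose_test, correlation_analysis, mann_whitney
from .nbs import NBSConfig, NBSResult, nbs_test
from .preprocess import (
    Recording,
    amplitude_artefact_filter,
    epoch_segments,
    meets_inclusion,
    valid_segments,
)
from .spectral import ConnectivityMatrix, EdgeMask, dbwpli, global_dbwpli, masked_mean, taper_fft
from scipy import stats as _sps

logger = logging.getLogger("alphaconn")

__all__ = ["PipelineConfig", "RunReport", "analyze_cohort", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; see `from_file` for the file layout."""

    cohort_csv: str
    out_dir: str
    epoch_length: float = 1.0
    overlap: float = 0.5
    amplitude_threshold: float = 200.0
    min_epochs: int = 120
    band: tuple[float, float] = (7.0, 8.0)
    edge_mask: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    nbs: dict[str, Any] = field(default_factory=dict)
    correlations: list[dict[str, Any]] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"pipeline config {path} must be a mapping")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.band = tuple(cfg.band)  # type: ignore[assignment]
        cfg.comparisons = [tuple(c) for c in cfg.comparisons]  # type: ignore[assignment]
        if cfg.band[0] > cfg.band[1]:
            raise ValueError("band must satisfy f_lo <= f_hi")
        base = path.parent
        cfg.cohort_csv = str((base / cfg.cohort_csv).resolve())
        if cfg.edge_mask:
            cfg.edge_mask = str((base / cfg.edge_mask).resolve())
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All per-subject and group-level outputs of one pipeline run."""

    subjects: pd.DataFrame  # per-subject epoch counts, inclusion, summaries
    matrices: dict[str, ConnectivityMatrix]
    global_tests: dict[str, TestResult]
    nbs_results: dict[str, NBSResult]
    correlations: dict[str, pd.DataFrame]
    config_hash: str = ""
    seed: int = 0

    @property
    def included(self) -> pd.DataFrame:
        return self.subjects[self.subjects["included"]]


def _preprocess_one(
    recording: Recording,
    epoch_length: float,
    overlap: float,
    amplitude_threshold: float,
) -> tuple[int, Any]:
    segments = valid_segments(recording)
    epochs = epoch_segments(recording, segments, epoch_length=epoch_length, overlap=overlap)
    clean = amplitude_artefact_filter(epochs, threshold=amplitude_threshold)
    return clean.n_epochs, clean


def analyze_cohort(
    recordings: dict[str, Recording],
    cohort: pd.DataFrame,
    *,
    epoch_length: float = 1.0,
    overlap: float = 0.5,
    amplitude_threshold: float = 200.0,
    min_epochs: int = 120,
    band: tuple[float, float] = (7.0, 8.0),
    edge_mask: EdgeMask | None = None,
    comparisons: list[tuple[str, str]] | None = None,
    nbs_kwargs: dict[str, Any] | None = None,
    correlations: list[dict[str, Any]] | None = None,
    seed: int = 0,
) -> RunReport:
    """Run the full analysis on in-memory recordings and a cohort table.

    ``cohort`` needs columns ``subject`` and ``group``; trait columns are
    passed through to the correlation analyses.  Subjects failing the
    inclusion rule (<= ``min_epochs`` clean epochs) are excluded with a
    reason and take no part in group statistics.
    """
    if "subject" not in cohort.columns or "group" not in cohort.columns:
        raise ValueError("cohort table must have 'subject' and 'group' columns")
    rows = []
    matrices: dict[str, ConnectivityMatrix] = {}
    for _, crow in cohort.iterrows():
        sid = str(crow["subject"])
        rec = recordings[sid]
        t0 = time.perf_counter()
        n_clean, clean = _preprocess_one(rec, epoch_length, overlap, amplitude_threshold)
        included = meets_inclusion(n_clean, min_epochs)
        row = dict(crow)
        row.update(
            n_epochs=n_clean,
            included=included,
            exclusion_reason="" if included else f"insufficient epochs ({n_clean} <= {min_epochs})",
            dbwpli_global=np.nan,
            dbwpli_selected=np.nan,
        )
        if included:
            spec = taper_fft(clean)
            m = dbwpli(spec, band)
            matrices[sid] = m
            row["dbwpli_global"] = global_dbwpli(m)
            if edge_mask is not None:
                row["dbwpli_selected"] = masked_mean(m, edge_mask)
        logger.debug("subject %s: %d epochs in %.2fs", sid, n_clean, time.perf_counter() - t0)
        rows.append(row)
    subjects = pd.DataFrame(rows)
    inc = subjects[subjects["included"]]

    # group comparisons of global connectivity: dispatcher + rank test, and NBS
    global_tests: dict[str, TestResult] = {}
    nbs_results: dict[str, NBSResult] = {}
    nbs_cfg = NBSConfig(seed=seed, **(nbs_kwargs or {}))
    for ga, gb in comparisons or []:
        a_ids = inc.loc[inc["group"] == ga, "subject"].tolist()
        b_ids = inc.loc[inc["group"] == gb, "subject"].tolist()
        key = f"{ga}_vs_{gb}"
        if len(a_ids) < 2 or len(b_ids) < 2:
            logger.warning("comparison %s skipped: too few included subjects", key)
            continue
        va = inc.loc[inc["group"] == ga, "dbwpli_global"].to_numpy()
        vb = inc.loc[inc["group"] == gb, "dbwpli_global"].to_numpy()
        if len(va) >= 3 and len(vb) >= 3 and choose_test(va, vb) == "t-test":
            t, p = _sps.ttest_ind(va, vb)
            global_tests[key] = TestResult(
                statistic="t", value=float(t), p=float(p), tails=2,
                n1=len(va), n2=len(vb),
            )
        else:
            global_tests[key] = mann_whitney(va, vb, tails=2)
        nbs_results[key] = nbs_test(
            [matrices[s] for s in a_ids], [matrices[s] for s in b_ids], nbs_cfg
        )

    # brain-behaviour correlations
    corr_tables: dict[str, pd.DataFrame] = {}
    for spec_d in correlations or []:
        name = spec_d.get("name") or "_".join(spec_d.get("groups") or ["all"])
        measures = spec_d.get("measures") or {"global": "dbwpli_global"}
        corr_tables[name] = correlation_analysis(
            inc,
            spec_d.get("groups"),
            measures,
            spec_d["scales"],
            fdr_q=spec_d.get("fdr_q"),
            winsorize=bool(spec_d.get("winsorize", False)),
        )
    return RunReport(
        subjects=subjects,
        matrices=matrices,
        global_tests=global_tests,
        nbs_results=nbs_results,
        correlations=corr_tables,
        seed=seed,
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """File-driven pipeline run; writes all artifacts under ``cfg.out_dir``."""
    cohort = pd.read_csv(cfg.cohort_csv)
    if "recording" not in cohort.columns:
        raise ValueError("cohort CSV must have a 'recording' path column")
    base = Path(cfg.cohort_csv).parent
    recordings: dict[str, Recording] = {}
    for _, row in cohort.iterrows():
        sid = str(row["subject"])
        rec = aio.read_recording(base / row["recording"])
        ann_path = row.get("annotations")
        if isinstance(ann_path, str) and ann_path:
            rec.annotations = aio.read_annotations(base / ann_path)
        else:
            logger.warning("subject %s: no annotation file; treating whole recording as valid", sid)
        recordings[sid] = rec
    mask = None
    if cfg.edge_mask:
        labels = next(iter(recordings.values())).channel_labels
        mask = aio.read_edge_mask(cfg.edge_mask, labels)

    report = analyze_cohort(
        recordings,
        cohort.drop(columns=[c for c in ("recording", "annotations") if c in cohort.columns]),
        epoch_length=cfg.epoch_length,
        overlap=cfg.overlap,
        amplitude_threshold=cfg.amplitude_threshold,
        min_epochs=cfg.min_epochs,
        band=cfg.band,
        edge_mask=mask,
        comparisons=cfg.comparisons,
        nbs_kwargs=cfg.nbs,
        correlations=cfg.correlations,
        seed=cfg.seed,
    )
    report.config_hash = cfg.config_hash()
    _write_report(report, cfg)
    return report


def _write_report(report: RunReport, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": report.config_hash, "seed": cfg.seed}
    report.subjects.to_csv(out / "subjects.csv", index=False)
    for sid, m in report.matrices.items():
        aio.write_connectivity(m, out / f"connectivity_{sid}.csv")
    tests_json = {
        key: {
            "statistic": t.statistic, "value": t.value, "z": t.z, "p": t.p,
            "p_mode": t.p_mode, "r": t.effect_r, "n1": t.n1, "n2": t.n2,
        }
        for key, t in report.global_tests.items()
    }
    nbs_json = {
        key: {
            "components": [
                {"edges": c.edges, "extent": c.extent, "intensity": c.intensity, "p": c.p_value}
                for c in r.components
            ],
            "n_permutations": len(r.null_max),
            "significant": [c.extent for c in r.significant],
        }
        for key, r in report.nbs_results.items()
    }
    (out / "report.json").write_text(
        json.dumps({"provenance": prov, "global_tests": tests_json, "nbs": nbs_json}, indent=2)
    )
    for key, r in report.nbs_results.items():
        np.savetxt(out / f"nbs_null_{key}.csv", r.null_max, delimiter=",", header="max_component", comments="")
    for name, table in report.correlations.items():
        table.to_csv(out / f"correlations_{name}.csv", index=False)
    logger.info("pipeline outputs written to %s (config %s)", out, report.config_hash)
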