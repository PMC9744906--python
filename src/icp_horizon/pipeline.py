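"""End-to-end orchestration: simulate -> qc -> segment -> featurize ->
benchmark -> explain, under one structured config and one master seed.

The master seed deterministically derives one sub-seed per stage, so a
single integer reproduces every delimited output byte-for-byte.  All
intermediate artifacts are plain delimited text (or JSON sidecars) so any
stage can be re-run standalone; a manifest records the config, the derived
seeds and a content hash of every written file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import explain, qc
from .features import CHANNEL_SETS, build_tables
from .modeling import FAMILIES, benchmark
from .records import EffectConfig, VitalsRecord, write_cohort
from .segmentation import Rejection, Segment, segment_record
from .synthgen import (ArtifactConfig, CohortConfig, MissingnessConfig,
                       generate_cohort)

log = logging.getLogger("icp_horizon")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, with clinical defaults."""

    # clinical framework
    icp_threshold: float = 20.0        # cm H2O
    event_duration: int = 10           # min
    independence_gap: int = 300        # min
    control_duration: int = 360        # min
    washout: int = 60                  # min
    record_len: int = 240              # min
    window_len: int = 30               # min
    n_windows: int = 8
    # qc
    missing_limit: float = 0.10
    wide_k: float = 2.0
    wide_block: int = 5                # min
    narrow_rel: float = 0.30
    # cohort
    n_patients: int = 22
    segments_per_patient: int = 10
    case_fraction: float = 1.0 / 11.0
    effect_magnitude: float = 1.0
    # modeling
    train_frac: float = 0.70
    n_iter: int = 10
    budget: int = 25
    threshold: float = 0.5
    families: tuple[str, ...] = FAMILIES
    group_by_patient: bool = False
    # explain
    top_k: int = 20
    channels: str = "full"             # "full" | "bp_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_windows * self.window_len != self.record_len:
            raise ValueError("n_windows * window_len must equal record_len")
        if self.channels not in CHANNEL_SETS:
            raise ValueError(f"channels must be one of {set(CHANNEL_SETS)}")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.record_len < 240:
            raise ValueError("record_len < 240 cannot host analysis records")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {unknown}")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_patients=self.n_patients,
            segments_per_patient=self.segments_per_patient,
            case_fraction=self.case_fraction,
            record_len=self.record_len,
            control_duration=self.control_duration,
            washout=self.washout,
            effect=EffectConfig().scaled(self.effect_magnitude),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["families"] = list(d["families"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def derive_seeds(master: int) -> dict[str, int]:
    """Per-stage seeds derived deterministically from one master seed."""
    ss = np.random.SeedSequence(master)
    names = ("simulate", "benchmark")
    state = ss.generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing delimited outputs and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "seeds": seeds, "files": {}}

    log.info("simulate: %d patients", config.n_patients)
    records, truths = generate_cohort(config.n_patients,
                                      config.cohort_config(),
                                      seed=seeds["simulate"])
    write_cohort(out / "cohort.csv", records, truths)

    log.info("qc: correcting %d records", len(records))
    corrected, masks, reports = [], {}, []
    for rec in records:
        corr, mask = qc.correct_record(rec, block_len=config.wide_block,
                                       k=config.wide_k,
                                       rel_threshold=config.narrow_rel)
        corrected.append(corr)
        masks[rec.record_id] = mask
        reports.append(qc.adjudicate(rec, mask,
                                     missing_limit=config.missing_limit))
    qc_df = pd.DataFrame([r.as_dict() for r in reports])
    qc_df["missing_fraction"] = qc_df["missing_fraction"].map(json.dumps)
    qc_df.to_csv(out / "qc_reports.csv", index=False)

    log.info("segment")
    segments: list[Segment] = []
    rejections = []
    for rec in corrected:
        mask = masks[rec.record_id]
        segs, rejs = segment_record(rec)
        rejections.extend(rejs)
        for seg in segs:
            rep = qc.adjudicate(rec, mask, span=seg.span,
                                missing_limit=config.missing_limit)
            if rep.verdict == "pass":
                segments.append(seg)
            else:
                rejections.append(Rejection(rec.record_id, seg.anchor,
                                            f"qc_{rep.verdict}"))
    manifest["n_segments"] = len(segments)
    manifest["n_cases"] = sum(s.label == "case" for s in segments)
    pd.DataFrame([{
        "segment_id": s.segment_id, "patient_id": s.patient_id,
        "label": s.label, "anchor": s.anchor,
        "span_start": s.span[0], "span_end": s.span[1],
    } for s in segments]).to_csv(out / "segments_manifest.csv", index=False)

    log.info("featurize: %d segments, channels=%s", len(segments),
             config.channels)
    tables = build_tables(segments, channels=config.channels)
    for w, table in tables.items():
        table.to_csv(out / f"features_w{w}.csv", index=False)

    log.info("benchmark: families=%s iters=%d budget=%d", config.families,
             config.n_iter, config.budget)
    result = benchmark(tables, families=config.families,
                       n_iter=config.n_iter, train_frac=config.train_frac,
                       budget=config.budget, seed=seeds["benchmark"],
                       threshold=config.threshold,
                       group_by_patient=config.group_by_patient)
    result.raw.to_csv(out / "benchmark_raw.csv", index=False)
    result.summary.to_csv(out / "benchmark_summary.csv", index=False)

    if "xgb" in config.families:
        log.info("explain")
        summary = explain.summarize_attributions(result, top_k=config.top_k)
        hm = explain.heatmap(summary)
        hm.counts.to_csv(out / "heatmap_signals.csv")
        hm.channel_counts.to_csv(out / "heatmap_channels.csv")
        for w, imp in summary.averaged.items():
            imp.sort_values(ascending=False).head(config.top_k).to_csv(
                out / f"top_features_w{w}.csv", header=["mean_abs_shap"])
        explain.plot_heatmap(hm, str(out / "heatmap.png"))
        if 2 in summary.averaged:
            explain.plot_importance(summary.averaged[2],
                                    str(out / "importance_w2.png"))

    config.to_yaml(out / "config.yaml")
    for f in sorted(out.iterdir()):
        if f.suffix in {".csv", ".yaml", ".json"}:
            manifest["files"][f.name] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest
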