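"""End-to-end driver: simulate → preprocess → extract → select → evaluate.

A :class:`PipelineConfig` captures every knob of a run and round-trips
through YAML bit-exactly; ``run_pipeline`` executes the stages, persisting
each stage's artifact (feature CSVs, channel scores, selection schemes,
evaluation reports, the resolved config and a structured log) into the run
directory, so a run is reconstructible from the directory alone.  The
global seed is split into per-stage substreams so any stage can be rerun
in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pdeeg import evaluation as ev
from pdeeg.feature_table import FeatureTable, extract_features
from pdeeg.montages import iowa_like_montage, unm_like_montage
from pdeeg.preprocessing import PreprocessConfig, preprocess_recordings
from pdeeg.selection import (SelectionScheme, SplitSpec, combine_schemes,
                             select_channels, single_channel_scores)
from pdeeg.synthetic import EffectProfile, generate_cohort

_MONTAGES = {"unm": unm_like_montage, "iowa": iowa_like_montage}


@dataclass
class PipelineConfig:
    # cohort
    n_pd: int = 27
    n_control: int = 26
    montage: str = "unm"
    montage_b: str = "iowa"  # harmonization partner
    eye_states: tuple[str, ...] = ("open",)
    duration_s: float = 60.0
    fs: float = 500.0
    # planted effect
    effect_channels: tuple[str, ...] = ("Oz", "P8")
    effect_band: str = "beta"
    power_ratio: float = 4.0
    background_sd: float = 10.0
    per_subject_sd: float = 0.4
    # preprocessing
    f_lo: float = 0.1
    f_hi: float = 100.0
    notch_freqs: tuple[float, ...] = (60.0, 180.0)
    seg_len: int = 2000
    n_segments: int = 15
    # selection / evaluation
    methods: tuple[str, ...] = ("iir", "wavelet")
    train_fraction: float = 0.7
    threshold: float = 0.7
    models: tuple[str, ...] = ("svm",)
    # bookkeeping
    seed: int = 0
    write_feature_csv: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(f_lo=self.f_lo, f_hi=self.f_hi,
                                notch_freqs=tuple(self.notch_freqs),
                                seg_len=self.seg_len, n_segments=self.n_segments)

    def effect(self) -> EffectProfile:
        return EffectProfile(target_channels=tuple(self.effect_channels),
                             band=self.effect_band, power_ratio=self.power_ratio,
                             background_sd=self.background_sd,
                             per_subject_sd=self.per_subject_sd)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)]


def write_report_tables(reports: list[ev.EvaluationReport], out_dir: str | Path) -> Path:
    """Write the long report CSV plus a models×schemes accuracy grid."""
    if not reports:
        raise ValueError("no reports to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([r.to_dict() for r in reports])
    frame["hyperparameters"] = frame["hyperparameters"].map(json.dumps)
    frame.to_csv(out_dir / "reports.csv", index=False)
    grid = frame.pivot_table(index="scheme", columns="model", values="accuracy")
    grid.to_csv(out_dir / "accuracy_grid.csv")
    return out_dir / "reports.csv"


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    Idempotent for a fixed config/seed: rerunning writes identical reports.
    Any stage failure raises with the stage name; artifacts written so far
    stay on disk for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    seeds = _stage_seeds(config.seed)
    log: list[dict] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log.append({"stage": name, "error": str(exc)})
                (out / "log.json").write_text(json.dumps(log, indent=1))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
            return result
        return deco

    montage_a = _MONTAGES[config.montage]()
    montage_b = _MONTAGES[config.montage_b]()

    cohort = stage("simulate")(lambda: generate_cohort(
        config.n_pd, config.n_control, montage_a, config.effect(),
        eye_states=tuple(config.eye_states), duration_s=config.duration_s,
        fs=config.fs, seed=seeds[0], cohort_name=config.montage))

    pre = config.preprocess_config()
    clean = stage("preprocess")(lambda: preprocess_recordings(cohort, montage_a, montage_b, pre))

    tables: dict[str, FeatureTable] = {}
    for method in config.methods:
        tables[method] = stage(f"extract[{method}]")(
            lambda m=method: extract_features(clean, m, pre))
        if config.write_feature_csv:
            tables[method].to_csv(out / f"features_{method}.csv")

    split = SplitSpec(train_fraction=config.train_fraction, seed=seeds[1])
    schemes: list[SelectionScheme] = []
    score_rows = []
    for method, table in tables.items():
        scores = stage(f"score[{method}]")(
            lambda t=table: single_channel_scores(t, split))
        score_rows += [{"channel": s.channel, "method": s.method, "r2": s.r2,
                        "seed": s.split_seed, "missing_reason": s.missing_reason}
                       for s in scores]
        schemes.append(select_channels(scores, config.threshold, name=method))
    pd.DataFrame(score_rows).to_csv(out / "channel_scores.csv", index=False)

    if len(schemes) == 2:
        schemes.append(combine_schemes(schemes[0], schemes[1], "union"))
        schemes.append(combine_schemes(schemes[0], schemes[1], "intersection"))
    for s in schemes:
        (out / f"scheme_{s.provenance}.txt").write_text("\n".join(s.channels) + "\n")
        (out / f"scheme_{s.provenance}.json").write_text(json.dumps(
            {"name": s.name, "channels": list(s.channels), "provenance": s.provenance,
             "threshold": s.threshold}, indent=1))

    reports: list[ev.EvaluationReport] = []
    eval_split = SplitSpec(train_fraction=config.train_fraction, seed=seeds[2])
    for model in config.models:
        for s in schemes:
            if not s.channels:
                continue
            table = tables[s.provenance] if s.provenance in tables else tables[config.methods[0]]
            reports.append(stage(f"evaluate[{model},{s.provenance}]")(
                lambda t=table, sch=s, m=model: ev.evaluate_holdout(
                    t, sch, ev.ModelConfig(m), eval_split)))
    if reports:
        write_report_tables(reports, out)
        (out / "reports.json").write_text(json.dumps(
            [r.to_dict() for r in reports], indent=1))

    (out / "log.json").write_text(json.dumps(
        {"config_hash": config.digest(), "stages": log}, indent=1))
    return out
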