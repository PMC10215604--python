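"""End-to-end orchestration: records -> features -> GA search -> report.

A run executes four stages in order: preprocessing (denoise, segment,
z-score), per-lead feature extraction into a cache, genetic search over
lead/length combinations, and final evaluation of the winning chromosome on
the held-out test patients. All randomness derives from one global seed; the
feature cache is immutable once written, so a run can resume from it.

The module also hosts the comparison harnesses: scoring a fixed list of
chromosomes (e.g. the twelve single-lead codes plus the all-lead code)
under one shared head and split, and the two controlled ablations (lead
attention vs pure MLP; weighted vs plain cross-entropy) on identical cached
features.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cache import FeatureCache
from .fem import TrainConfig, populate_cache
from .ga import (Chromosome, Evaluator, EvaluatedIndividual, FitnessConfig,
                 GaConfig, evolve)
from .io_dump import read_records
from .metrics import MetricsReport
from .synthetic import (SynthConfig, arrhythmia_synth_config,
                        generate_records, mi_synth_config, split_inter_patient)

__all__ = ["RunConfig", "RunResult", "run_full", "compare_leads",
           "ablate_lam", "ablate_loss"]

log = logging.getLogger("galslo")


@dataclass
class RunConfig:
    """Resolved configuration for one end-to-end run."""

    task: str = "mi"                       # 'mi' (2-class) or 'arrhythmia' (5-class)
    data_dir: str | None = None            # plain array-dump directory, or None
    synth: SynthConfig | None = None       # synthetic source when data_dir is None
    lengths: tuple[int, ...] = (1, 2, 3)
    leads: tuple[int, ...] = tuple(range(1, 13))
    width_scale: float = 1.0
    fem_epochs: int = 40
    head: str = "lam"
    loss: str = "weighted_ce"
    ga: GaConfig = field(default_factory=GaConfig)
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    head_kwargs: dict = field(default_factory=dict)
    max_segments_per_record: int | None = None
    out_dir: str | None = None
    seed: int = 0

    def resolved_synth(self) -> SynthConfig:
        if self.synth is not None:
            return self.synth
        maker = mi_synth_config if self.task == "mi" else arrhythmia_synth_config
        return maker(seed=self.seed)


@dataclass
class RunResult:
    best: EvaluatedIndividual
    history: list[dict]
    report: MetricsReport
    cache: FeatureCache
    out_dir: Path | None


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def _done(name: str, t0: float):
    log.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)


def run_full(cfg: RunConfig) -> RunResult:
    """Execute preprocessing, feature caching, GA search and final report."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    cache_path = out_dir / "cache.h5" if out_dir else None

    if cache_path and cache_path.exists():
        t0 = _stage("load cached features")
        cache = FeatureCache.load(cache_path)
        _done("load cached features", t0)
    else:
        t0 = _stage("acquire records")
        if cfg.data_dir:
            records = read_records(cfg.data_dir)
        else:
            records = generate_records(cfg.resolved_synth())
        train, test = split_inter_patient(records, 0.8, seed=cfg.seed)
        _done("acquire records", t0)

        t0 = _stage("preprocess + feature extraction")
        fem_cfg = TrainConfig(epochs=cfg.fem_epochs, loss=cfg.loss, seed=cfg.seed)
        cache = populate_cache(records, cfg.task, cfg.lengths, cfg.leads,
                               fem_cfg, width_scale=cfg.width_scale,
                               split=(train, test),
                               max_segments_per_record=cfg.max_segments_per_record)
        if cache_path:
            cache.save(cache_path)
        _done("preprocess + feature extraction", t0)

    t0 = _stage("genetic search")
    ga_cfg = dataclasses.replace(cfg.ga, lengths=cfg.lengths, leads=cfg.leads,
                                 seed=cfg.seed)
    evaluator = Evaluator(cache, head=cfg.head, fitness_cfg=cfg.fitness,
                          seed=cfg.seed, head_kwargs=cfg.head_kwargs)
    best, history = evolve(evaluator, ga_cfg)
    _done("genetic search", t0)

    t0 = _stage("final evaluation")
    report, _, _ = evaluator.final_report(best.chromosome)
    _done("final evaluation", t0)

    if out_dir:
        (out_dir / "config.json").write_text(json.dumps(
            {"version": __version__,
             **{k: _jsonable(v) for k, v in dataclasses.asdict(cfg).items()}},
            indent=2, default=str))
        (out_dir / "history.json").write_text(json.dumps(history, indent=2))
        (out_dir / "best_chromosome.txt").write_text(str(best.chromosome) + "\n")
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.txt").write_text(report.to_text() + "\n")
        report.to_frame().to_csv(out_dir / "report.csv")
    return RunResult(best=best, history=history, report=report, cache=cache,
                     out_dir=out_dir)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, tuple):
        return list(v)
    return v


def compare_leads(cache: FeatureCache, chromosomes: list[Chromosome],
                  head: str = "lam", seed: int = 0,
                  head_kwargs: dict | None = None) -> pd.DataFrame:
    """Score each chromosome on the shared test split with one head type.

    Returns one row per chromosome with its bracket coding and macro
    metrics — the single-lead / all-lead comparison harness.
    """
    evaluator = Evaluator(cache, head=head, seed=seed, head_kwargs=head_kwargs)
    rows = []
    for c in chromosomes:
        report, _, _ = evaluator.final_report(c)
        rows.append({"coding": f"[{c}]", **{m: report.macro[m]
                                            for m in ("Sen", "Spe", "Ppr", "Acc", "F1")}})
    df = pd.DataFrame(rows)
    df[["Sen", "Spe", "Ppr", "Acc", "F1"]] = \
        df[["Sen", "Spe", "Ppr", "Acc", "F1"]].round(2)
    return df


def ablate_lam(cache: FeatureCache, chromosome: Chromosome, seed: int = 0,
               head_kwargs: dict | None = None) -> dict[str, MetricsReport]:
    """Attention ablation: identical features, LAM head vs pure-MLP head."""
    evaluator = Evaluator(cache, head="lam", seed=seed, head_kwargs=head_kwargs)
    out = {}
    for head in ("lam", "mlp"):
        report, _, _ = evaluator.final_report(chromosome, head=head)
        out[head] = report
    return out


def ablate_loss(cache: FeatureCache, chromosome: Chromosome, seed: int = 0,
                head_kwargs: dict | None = None) -> dict[str, MetricsReport]:
    """Loss ablation: weighted vs plain cross-entropy head training on
    identical cached features."""
    out = {}
    for name, weighted in (("weighted", True), ("plain", False)):
        kwargs = dict(head_kwargs or {})
        kwargs["weighted"] = weighted
        evaluator = Evaluator(cache, head="lam", seed=seed, head_kwargs=kwargs)
        report, _, _ = evaluator.final_report(chromosome)
        out[name] = report
    return out
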