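"""End-to-end orchestration: simulate -> hazards -> behavior -> encoding -> stats.

A :class:`RunConfig` fully determines a run.  A single master seed fans out to
per-stage seeds through a counter-based derivation, so any stage can be
re-run independently yet reproducibly.  Every stage writes plain delimited
tables with JSON sidecars; a stage is skipped when its outputs already exist
for the same configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_models, cluster_stats, encoding, hazard, paradigm, synthetic_data

logger = logging.getLogger("fpseq")

_STAGE_INDEX = {
    "simulate": 1,
    "hazards": 2,
    "behavior": 3,
    "encoding": 4,
    "cluster": 5,
}


def derive_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    """Counter-based per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_INDEX.get(stage, 99), int(extra)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    master_seed: int = 0
    n_participants: int = 31
    paradigm_mode: str = "idealized"
    hazard_source: str = "idealized"  # 'idealized' design hazards or 'empirical'
    behavior: synthetic_data.BehaviorGenParams = field(
        default_factory=synthetic_data.BehaviorGenParams
    )
    response_scale: str = "raw"
    # encoding stage (desk-scale defaults)
    n_encoding_participants: int = 4
    n_encoding_trials: int = 40
    neural_noise_sd: float = 1.0
    neural_amplitude: float = 0.05
    encoding_lambda: float = 1.0
    encoding_models: tuple[str, ...] = ("C", "U+C+UxC")
    grid_shape: tuple[int, int] = (8, 8)
    # cluster stage
    cluster_alpha: float = 0.05
    cluster_forming_alpha: float = 0.025
    n_perm: int = 500
    out_dir: str = "fpseq_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["behavior"] = asdict(self.behavior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "behavior" in d and isinstance(d["behavior"], dict):
            d["behavior"] = synthetic_data.BehaviorGenParams(**d["behavior"])
        for key in ("encoding_models", "grid_shape"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_is_cached(out: Path, stage: str, cfg_hash: str, files: list[Path]) -> bool:
    marker = out / f".{stage}.hash"
    return marker.exists() and marker.read_text() == cfg_hash and all(f.exists() for f in files)


def _mark_stage(out: Path, stage: str, cfg_hash: str) -> None:
    (out / f".{stage}.hash").write_text(cfg_hash)


def stage_simulate(config: RunConfig, out: Path) -> pd.DataFrame:
    """Generate sessions, plant reaction times, inject false alarms."""
    behavior_path = out / "behavior.tsv"
    cfg_hash = config.config_hash()
    if _stage_is_cached(out, "simulate", cfg_hash, [behavior_path]):
        logger.info("simulate: cached")
        return paradigm.read_trial_table(behavior_path)
    t0 = time.time()
    sessions = paradigm.generate_sessions(
        config.n_participants, derive_seed(config.master_seed, "simulate"),
        config.paradigm_mode,
    )
    hz_u, hz_c = _hazard_set(config, sessions)
    table = synthetic_data.simulate_reaction_times(
        sessions, hz_u, hz_c, config.behavior,
        derive_seed(config.master_seed, "simulate", 1),
    )
    table = synthetic_data.inject_false_alarms(
        table, config.behavior.false_alarm_rate,
        derive_seed(config.master_seed, "simulate", 2),
    )
    paradigm.write_trial_table(table, behavior_path)
    _mark_stage(out, "simulate", cfg_hash)
    logger.info("simulate: %d rows in %.1f s", len(table), time.time() - t0)
    return table


def _hazard_set(config: RunConfig, sessions: pd.DataFrame):
    if config.hazard_source == "idealized":
        return hazard.idealized_hazards()
    return hazard.empirical_hazards(sessions)


def stage_hazards(config: RunConfig, out: Path, sessions: pd.DataFrame):
    """Write the unconditional and conditional hazard series."""
    hz_u, hz_c = _hazard_set(config, sessions)
    hdir = out / "hazards"
    hdir.mkdir(exist_ok=True)
    hazard.write_hazard(hz_u, hdir / "HF_U.tsv")
    for (block, ctx), hz in hz_c.items():
        hazard.write_hazard(hz, hdir / f"HF_C_block{block}_{ctx}.tsv")
    return hz_u, hz_c


def stage_behavior(config: RunConfig, out: Path, table: pd.DataFrame,
                   hz_u, hz_c) -> dict:
    """Regressor table, the FP1 model and the four FP2 models, comparison."""
    t0 = time.time()
    reg = behavior_models.build_regressor_table(table, hz_u, hz_c)
    fp1 = reg[reg["position"] == "FP1"]
    fit_fp1 = behavior_models.fit_mixed_model(
        fp1, ("HF_U",), ("participant",), config.response_scale, label="FP1~HF_U"
    )
    fits = behavior_models.fit_fp2_model_set(reg, config.response_scale)
    comparison = behavior_models.compare_models(list(fits.values()))
    result = {
        "fp1": fit_fp1.to_dict(),
        "fp2": {lab: f.to_dict() for lab, f in fits.items()},
        "comparison": {
            "ranking_aic": list(comparison.ranking_aic),
            "ranking_bic": list(comparison.ranking_bic),
            "lr_tests": comparison.lr_tests,
        },
        "sequential_effect": behavior_models.sequential_effect_summary(table)
        .to_dict(orient="records"),
    }
    (out / "behavior_fits.json").write_text(json.dumps(result, indent=1))
    comparison.table.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    logger.info("behavior: fits done in %.1f s", time.time() - t0)
    return result


def stage_encoding(config: RunConfig, out: Path, table: pd.DataFrame,
                   hz_u, hz_c) -> dict[str, np.ndarray]:
    """Per-participant encoding scores for each model set (+ shuffled control)."""
    t0 = time.time()
    params = synthetic_data.default_neural_params(
        noise_sd=config.neural_noise_sd, amplitude=config.neural_amplitude,
        grid_shape=config.grid_shape,
    )
    pids = sorted(table["participant_id"].unique())[: config.n_encoding_participants]
    score_maps: dict[str, list[np.ndarray]] = {m: [] for m in config.encoding_models}
    score_maps["shuffled"] = []
    for i, pid in enumerate(pids):
        sub = table[table["participant_id"] == pid]
        trials = synthetic_data.simulate_source_signals(
            sub, hz_u, hz_c, params,
            derive_seed(config.master_seed, "encoding", i),
        )[: config.n_encoding_trials]
        for m in config.encoding_models:
            score, _ = encoding.loo_encode(
                trials, config.encoding_lambda, params.lagspec,
                encoding.MODEL_SETS[m],
            )
            score_maps[m].append(score.channel_means)
        ctrl, _ = encoding.shuffled_control(
            trials, config.encoding_lambda, params.lagspec,
            encoding.MODEL_SETS[config.encoding_models[-1]],
            seed=derive_seed(config.master_seed, "encoding", 1000 + i),
        )
        score_maps["shuffled"].append(ctrl.channel_means)
    maps = {m: np.vstack(v) for m, v in score_maps.items()}
    edir = out / "encoding"
    edir.mkdir(exist_ok=True)
    for m, arr in maps.items():
        name = m.replace("+", "_")
        pd.DataFrame(arr).to_csv(edir / f"scores_{name}.tsv", sep="\t", index=False)
    (edir / "manifest.json").write_text(json.dumps({
        "models": list(maps), "lambda": config.encoding_lambda,
        "participants": [int(p) for p in pids],
        "n_trials": config.n_encoding_trials,
        "grid_shape": list(config.grid_shape),
    }, indent=1))
    logger.info("encoding: %d participants in %.1f s", len(pids), time.time() - t0)
    return maps


def stage_cluster(config: RunConfig, out: Path, maps: dict[str, np.ndarray]) -> dict:
    """Group-level cluster tests: full model vs 0 and full vs C-only."""
    t0 = time.time()
    graph = cluster_stats.lattice_adjacency(config.grid_shape)
    full = config.encoding_models[-1]
    results = {}
    res = cluster_stats.cluster_permutation_test(
        maps[full], graph, alpha=config.cluster_alpha,
        cluster_alpha=config.cluster_forming_alpha, n_perm=config.n_perm,
        seed=derive_seed(config.master_seed, "cluster"),
    )
    results[f"{full}_vs_0"] = res.to_dict()
    if len(config.encoding_models) > 1:
        other = config.encoding_models[0]
        paired = cluster_stats.paired_map_test(
            maps[full], maps[other], graph, alpha=config.cluster_alpha,
            cluster_alpha=config.cluster_forming_alpha, n_perm=config.n_perm,
            seed=derive_seed(config.master_seed, "cluster", 1),
        )
        results[f"{full}_vs_{other}"] = paired.to_dict()
    (out / "cluster_results.json").write_text(json.dumps(results, indent=1))
    logger.info("cluster: done in %.1f s", time.time() - t0)
    return results


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute all stages in dependency order and emit the run report."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")

    table = stage_simulate(config, out)
    hz_u, hz_c = stage_hazards(config, out, table)
    behavior = stage_behavior(config, out, table, hz_u, hz_c)
    maps = stage_encoding(config, out, table, hz_u, hz_c)
    clusters = stage_cluster(config, out, maps)

    report = {
        "config_hash": config.config_hash(),
        "seeds": {s: derive_seed(config.master_seed, s) for s in _STAGE_INDEX},
        "behavior": behavior,
        "encoding_mean_scores": {
            m: float(np.nanmean(arr)) for m, arr in maps.items()
        },
        "cluster": clusters,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
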