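"""Cycle and scenario orchestration.

One breeding cycle is: random pairing of the current parents -> biparental
crosses -> single-seed descent to F4 -> phenotyping and array genotyping of
the F4 lines -> model training on the sliding history window -> candidate
scoring -> truncation selection -> the selected lines become next cycle's
parents. Per-cycle summaries over replicates accumulate into a long-format
results table.

Randomness is organised as one root seed per replicate with named child
streams per cycle and operation, so any cycle is reproducible in isolation
and scenarios sharing a replicate index share founders and all pre-selection
randomness (common random numbers across the grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import breeding, models, selection, trait
from .config import ScenarioConfig
from .genome import (
    MarkerPanel,
    Population,
    HistoryParams,
    build_genetic_map,
    genotype_matrix,
    select_marker_panel,
    simulate_founders,
)

__all__ = ["run_cycle", "run_replicate", "run_scenario", "run_grid", "summarize"]

logger = logging.getLogger("soysim")

GS_MODES = ("GBLUP", "BayesA", "BayesB", "FLM", "RF")

SUMMARY_COLUMNS = [
    "model", "strategy", "intensity", "design", "replicate", "cycle",
    "mean_tbv", "mean_phenotype", "genetic_variance", "realized_h2",
    "accuracy", "mean_heterozygosity", "n_selected", "model_used",
]


@dataclass
class ReplicateState:
    """Mutable state threaded through the cycles of one replicate."""

    parents: Population
    arch: trait.TraitArchitecture
    panel: MarkerPanel
    history: list = field(default_factory=list)  # (cycle, M, y) tuples
    cycle: int = 0


def _streams(cfg: ScenarioConfig, rep: int, cycle: int) -> dict:
    ss = np.random.SeedSequence([cfg.seed, rep, cycle])
    kids = ss.spawn(3)
    return {
        "breeding": np.random.default_rng(kids[0]),
        "phenotype": np.random.default_rng(kids[1]),
        "scoring": np.random.default_rng(kids[2]),
    }


def _summary_row(cfg, rep, cycle, pop, scores, n_selected, model_used):
    var_y = float(np.var(pop.phenotype)) if pop.phenotype is not None else np.nan
    gv = trait.genetic_variance(pop)
    acc = (
        models.prediction_accuracy(scores, pop.tbv)
        if scores is not None
        else float("nan")
    )
    return {
        "model": cfg.model,
        "strategy": cfg.strategy,
        "intensity": cfg.intensity,
        "design": cfg.design,
        "replicate": rep,
        "cycle": cycle,
        "mean_tbv": float(np.mean(pop.tbv)),
        "mean_phenotype": float(np.mean(pop.phenotype)) if pop.phenotype is not None else np.nan,
        "genetic_variance": gv,
        "realized_h2": gv / var_y if var_y and var_y > 0 else np.nan,
        "accuracy": acc,
        "mean_heterozygosity": pop.mean_heterozygosity(),
        "n_selected": n_selected,
        "model_used": model_used,
    }


def _fit_model(cfg: ScenarioConfig, ts: models.TrainingSet, rng) -> models.PredictionModel:
    if cfg.model == "RF":
        return models.fit_rf(
            ts, n_trees=cfg.rf_trees, seed=int(rng.integers(2**31 - 1))
        )
    return models.fit_wgr(cfg.model, ts, tol=cfg.em_tol, max_iter=cfg.em_max_iter)


def _select(cfg: ScenarioConfig, scores, family_ids, ids) -> np.ndarray:
    frac = cfg.intensity_fraction
    if cfg.strategy == "AF":
        n = max(1, selection.round_half_up(frac * len(scores)))
        return selection.select_af(scores, n, ids=ids)
    if cfg.strategy == "WF":
        return selection.select_wf(scores, family_ids, frac, ids=ids)
    return selection.select_wpsf(
        scores, family_ids, frac, family_fraction=cfg.wpsf_family_fraction, ids=ids
    )


def run_cycle(state: ReplicateState, cfg: ScenarioConfig, rep: int) -> dict:
    """Advance one breeding cycle; returns the cycle's summary row."""
    cycle = state.cycle + 1
    rngs = _streams(cfg, rep, cycle)

    plan = breeding.pair_parents(state.parents.ids, cfg.n_families, rngs["breeding"])
    f1 = breeding.make_crosses(state.parents, plan, rngs["breeding"])
    f1.cycle = cycle
    f4 = breeding.ssd_advance(
        f1, cfg.family_size, cfg.selfing_rounds, rng=rngs["breeding"]
    )
    trait.compute_tbv(f4, state.arch)
    trait.simulate_phenotypes(f4, state.arch, season_index=cycle, rng=rngs["phenotype"])
    M = genotype_matrix(f4, state.panel)

    model_used = cfg.model
    scores = None
    if cfg.model in GS_MODES:
        if state.history:
            ts = models.assemble_training_window(
                state.history, cfg.window, cfg.max_training_records
            )
            fitted = _fit_model(cfg, ts, rngs["scoring"])
            scores = models.score_candidates(cfg.model, f4, model=fitted, M=M)
        else:
            # cold start: no completed cycle to train on yet
            model_used = "Pheno"
            scores = models.score_candidates("Pheno", f4)
            logger.info("%s rep %d cycle %d: cold start, phenotypic fallback",
                        cfg.key, rep, cycle)
    else:
        scores = models.score_candidates(cfg.model, f4, rng=rngs["scoring"])

    selected_ids = _select(cfg, scores, f4.family, f4.ids)
    row = _summary_row(cfg, rep, cycle, f4, scores, len(selected_ids), model_used)
    logger.info(
        "%s rep=%d cycle=%d mean=%.3f var=%.3f acc=%.3f",
        cfg.key, rep, cycle, row["mean_tbv"], row["genetic_variance"],
        row["accuracy"] if row["accuracy"] == row["accuracy"] else -1.0,
    )

    state.history.append((cycle, M, f4.phenotype.copy()))
    if len(state.history) > cfg.window:
        state.history.pop(0)
    sel_idx = np.searchsorted(f4.ids, np.sort(selected_ids))
    state.parents = f4.subset(sel_idx)
    state.cycle = cycle
    return row


def run_replicate(cfg: ScenarioConfig, rep: int) -> pd.DataFrame:
    """One full replicate: founders through ``n_cycles`` cycles."""
    init = np.random.SeedSequence([cfg.seed, rep, 0]).spawn(4)
    gmap = build_genetic_map(
        n_chr=cfg.genome.n_chr,
        mean_length_cm=cfg.genome.mean_length_cm,
        sites_per_chr=cfg.genome.sites_per_chr,
        total_bp=cfg.genome.total_bp,
        seed=init[0],
    )
    founders = simulate_founders(
        gmap, cfg.n_founders, HistoryParams(ne=cfg.genome.ne), seed=init[1]
    )
    arch = trait.assign_qtl_effects(
        gmap,
        founders,
        prop_qtl=cfg.trait.prop_qtl,
        target_var=cfg.trait.var_a,
        base_mean=cfg.trait.base_mean,
        var_gxe=cfg.trait.var_gxe,
        var_e=cfg.trait.var_e,
        seed=init[2],
    )
    panel = select_marker_panel(founders, gmap, cfg.genome.n_markers)
    trait.compute_tbv(founders, arch)
    trait.simulate_phenotypes(
        founders, arch, season_index=0, rng=np.random.default_rng(init[3])
    )
    rows = [_summary_row(cfg, rep, 0, founders, None, 0, "none")]

    state = ReplicateState(parents=founders, arch=arch, panel=panel)
    for _ in range(cfg.n_cycles):
        rows.append(run_cycle(state, cfg, rep))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _rep_checkpoint(out_dir: Path, cfg: ScenarioConfig, rep: int) -> Path:
    return out_dir / "checkpoints" / f"{cfg.key}_rep{rep}.csv"


def _run_rep_checkpointed(cfg: ScenarioConfig, rep: int, out_dir: Path | None):
    if out_dir is not None:
        ckpt = _rep_checkpoint(out_dir, cfg, rep)
        if ckpt.exists():
            df = pd.read_csv(ckpt)
            if len(df) == cfg.n_cycles + 1:  # complete replicate
                return df
        df = run_replicate(cfg, rep)
        ckpt.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(ckpt, index=False)
        return df
    return run_replicate(cfg, rep)


def run_scenario(
    cfg: ScenarioConfig, n_jobs: int = 1, out_dir=None
) -> pd.DataFrame:
    """All replicates of one scenario; deterministic given the root seed.

    When ``out_dir`` is given, each finished replicate is checkpointed to
    CSV and complete checkpoints are reused on a re-run (resume).
    """
    reps = list(range(cfg.n_replicates))
    if len(set(reps)) != len(reps):  # pragma: no cover - defensive
        raise ValueError("duplicate replicate seeds refused")
    out_dir = Path(out_dir) if out_dir is not None else None
    frames = Parallel(n_jobs=n_jobs)(
        delayed(_run_rep_checkpointed)(cfg, r, out_dir) for r in reps
    )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["replicate", "cycle"], ignore_index=True)


def run_grid(
    scenarios: list[ScenarioConfig], n_jobs: int = 1, out_dir=None
) -> pd.DataFrame:
    """Embarrassingly parallel sweep over (scenario, replicate) tasks.

    The merged table is sorted by scenario key, replicate and cycle, so the
    result is identical regardless of worker count or scheduling.
    """
    keys = [c.key for c in scenarios]
    if len(set(keys)) != len(keys):
        raise ValueError("scenario key collision refused")
    if not scenarios:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    out_dir = Path(out_dir) if out_dir is not None else None
    tasks = [(c, r) for c in scenarios for r in range(c.n_replicates)]
    frames = Parallel(n_jobs=n_jobs)(
        delayed(_run_rep_checkpointed)(c, r, out_dir) for c, r in tasks
    )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(
        ["model", "strategy", "intensity", "design", "replicate", "cycle"],
        ignore_index=True,
    )


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean trajectories per scenario cell and cycle."""
    keys = ["model", "strategy", "intensity", "design", "cycle"]
    vals = ["mean_tbv", "mean_phenotype", "genetic_variance", "realized_h2", "accuracy",
            "mean_heterozygosity"]
    return results.groupby(keys, as_index=False)[vals].mean()
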