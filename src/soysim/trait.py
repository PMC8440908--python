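"""Additive trait architecture, breeding values, and phenotypes.

Grain yield (t/ha) is simulated as an infinitesimal-style additive trait:
70% of all segregating sites carry a normal effect by default. Effects are
rescaled so the founder-population additive variance hits its target
exactly (sigma_a^2 = 25 at defaults) and an intercept anchors the founder
mean at 3.00 t/ha. Phenotypes add a non-heritable seasonal (GxE) deviate
and a residual, both Gaussian; the residual variance stays constant over
cycles, so heritability erodes as genetic variance is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneticMap, Population

__all__ = [
    "TraitArchitecture",
    "assign_qtl_effects",
    "compute_tbv",
    "simulate_phenotypes",
    "genetic_variance",
    "write_phenotype_table",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL set, scaled additive effects, and variance components."""

    qtl_indices: np.ndarray  # flat site indices carrying effects
    effects: np.ndarray  # t/ha per allele copy, same order as qtl_indices
    intercept: float
    base_mean: float
    var_a: float  # founder additive variance the effects were scaled to
    var_gxe: float
    var_e: float
    total_sites: int

    @property
    def h2(self) -> float:
        """Narrow-sense heritability implied by the variance components."""
        return self.var_a / (self.var_a + self.var_gxe + self.var_e)


def assign_qtl_effects(
    gmap: GeneticMap,
    founders: Population,
    prop_qtl: float = 0.70,
    target_var: float = 25.0,
    base_mean: float = 3.00,
    var_gxe: float = 49.0,
    var_e: float = 121.0,
    seed: int | None = None,
) -> TraitArchitecture:
    """Sample QTL effects and scale them to the founder additive variance.

    ``floor(prop_qtl * n_sites)`` sites are drawn genome-wide without
    replacement and given N(0,1) effects, which are then multiplied by a
    common factor so the (population) variance of founder true breeding
    values equals ``target_var`` exactly; the intercept is set so the
    founder mean equals ``base_mean``.
    """
    if not 0 < prop_qtl <= 1:
        raise ValueError("prop_qtl must be in (0, 1]")
    if var_gxe < 0 or var_e < 0:
        raise ValueError("variance components must be non-negative")
    rng = np.random.default_rng(seed)
    S = gmap.total_sites
    n_qtl = int(np.floor(prop_qtl * S))
    qtl = np.sort(rng.choice(S, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)

    raw = founders.dosage(qtl).astype(np.float64) @ effects
    v = raw.var()
    if v <= 0:
        raise ValueError("founders are monomorphic at all sampled QTL; cannot scale")
    scale = np.sqrt(target_var / v)
    effects *= scale
    intercept = base_mean - raw.mean() * scale
    return TraitArchitecture(
        qtl_indices=qtl,
        effects=effects,
        intercept=float(intercept),
        base_mean=base_mean,
        var_a=target_var,
        var_gxe=var_gxe,
        var_e=var_e,
        total_sites=S,
    )


def compute_tbv(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """True breeding values: intercept + sum of QTL effect × dosage.

    Also stored on the population. Deterministic.
    """
    if pop.gmap.total_sites != arch.total_sites:
        raise ValueError("population map does not match trait architecture")
    tbv = arch.intercept + pop.dosage(arch.qtl_indices).astype(np.float64) @ arch.effects
    pop.tbv = tbv
    return tbv


def simulate_phenotypes(
    pop: Population,
    arch: TraitArchitecture,
    season_index: int = 0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One unreplicated phenotype per individual for a given season.

    y = TBV + gxe + e with gxe ~ N(0, var_gxe) drawn independently per
    individual per season and e ~ N(0, var_e). The three components are
    stored on the population so the decomposition is exactly recoverable.
    """
    if pop.tbv is None:
        compute_tbv(pop, arch)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = pop.n_individuals
    gxe = rng.normal(0.0, np.sqrt(arch.var_gxe), size=n)
    eps = rng.normal(0.0, np.sqrt(arch.var_e), size=n)
    pop.gxe = gxe
    pop.phenotype = pop.tbv + gxe + eps
    # store the residual as recomputed from y so y - TBV - gxe = eps holds
    # bit-exactly (differs from the drawn deviate only by float rounding)
    pop.residual = pop.phenotype - pop.tbv - gxe
    eps = pop.residual
    return pd.DataFrame(
        {
            "cycle": pop.cycle,
            "season": season_index,
            "family": pop.family,
            "individual": pop.ids,
            "tbv": pop.tbv,
            "gxe": gxe,
            "residual": eps,
            "phenotype": pop.phenotype,
        }
    )


def genetic_variance(pop_or_tbv) -> float:
    """Population variance of TBV within the candidate set."""
    tbv = pop_or_tbv.tbv if isinstance(pop_or_tbv, Population) else np.asarray(pop_or_tbv)
    if tbv is None:
        raise ValueError("TBVs have not been computed")
    if len(tbv) < 2:
        raise ValueError("need at least 2 individuals")
    return float(np.var(tbv))


def write_phenotype_table(records: pd.DataFrame, path) -> None:
    cols = ["cycle", "family", "individual", "tbv", "gxe", "residual", "phenotype"]
    records[cols].to_csv(path, index=False)
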