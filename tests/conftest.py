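"""Shared fixtures. The expensive ones are session-scoped and reused:

* ``small_founders`` — 100 founders on a 4-chromosome genome, for unit tests.
* ``calibration_sim`` — 10,000 founders with the default trait variance
  components, for heritability calibration checks.
* ``trend_results`` — a scaled-down scenario grid (50 families x 10 lines,
  1,000 markers, 30 cycles, 5 replicates) exercising the full breeding loop.
"""

from dataclasses import replace

import numpy as np
import pytest

import soysim as ss
from soysim.config import GenomeParams, ScenarioConfig
from soysim.runner import run_grid


@pytest.fixture(scope="session")
def small_gmap():
    return ss.build_genetic_map(n_chr=4, sites_per_chr=150, seed=11)


@pytest.fixture(scope="session")
def small_founders(small_gmap):
    return ss.simulate_founders(small_gmap, 100, seed=12)


@pytest.fixture(scope="session")
def small_arch(small_gmap, small_founders):
    return ss.assign_qtl_effects(small_gmap, small_founders, seed=13)


@pytest.fixture(scope="session")
def calibration_sim():
    """Founder-cycle calibration at large n: map, founders, architecture,
    phenotypes for one season under the default variance components."""
    gmap = ss.build_genetic_map(n_chr=10, sites_per_chr=200, seed=21)
    founders = ss.simulate_founders(gmap, 10_000, seed=22)
    arch = ss.assign_qtl_effects(gmap, founders, seed=23)
    ss.compute_tbv(founders, arch)
    ss.simulate_phenotypes(founders, arch, seed=24)
    return gmap, founders, arch


TREND_BASE = ScenarioConfig(
    model="TBV",
    strategy="AF",
    intensity=10.0,
    n_families=50,
    family_size=10,
    n_cycles=30,
    n_replicates=5,
    seed=101,
    n_founders=200,
    genome=GenomeParams(n_chr=10, sites_per_chr=300, n_markers=1000),
    em_tol=1e-6,
    em_max_iter=150,
)


@pytest.fixture(scope="session")
def trend_results():
    """Scaled-down trend grid over models, strategies and intensities.

    Scenarios share replicate seeds (common random numbers), so paired
    comparisons across grid cells are well defined.
    """
    scenarios = [replace(TREND_BASE, model=m) for m in ("TBV", "GBLUP", "Pheno", "Random")]
    scenarios += [replace(TREND_BASE, model="GBLUP", strategy=s) for s in ("WF", "WPSF")]
    scenarios += [replace(TREND_BASE, model="GBLUP", intensity=2.5)]
    return run_grid(scenarios, n_jobs=1)


def cell(results, model, strategy, intensity):
    """Replicate-mean trajectory of one scenario cell, indexed by cycle."""
    sub = results[
        (results["model"] == model)
        & (results["strategy"] == strategy)
        & (results["intensity"] == intensity)
    ]
    return sub.groupby("cycle")[["mean_tbv", "genetic_variance", "accuracy"]].mean()
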