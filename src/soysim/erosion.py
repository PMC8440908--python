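"""Post-hoc statistics on simulation results.

Three analyses: (1) the number of cycles until a scenario's replicate-mean
genetic variance falls to 20% of its starting value (80% depleted);
(2) the per-cycle percent drift in genetic variance under random
selection, estimated by log-linear regression of variance on cycle; and
(3) an additive fixed-effects evaluation of the factors (prediction
model, strategy, intensity, population design) on replicate-level
population means at a chosen generation, with Tukey-Kramer multiple
comparisons and compact letter groupings at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "DepletionResult",
    "DriftEstimate",
    "FactorAnalysisResult",
    "cycles_to_depletion",
    "drift_rate",
    "factor_analysis",
]

FACTORS = ("model", "strategy", "intensity", "design")


@dataclass(frozen=True)
class DepletionResult:
    threshold: float
    cycle: int | None  # first cycle at/below (1-threshold) x initial variance
    censored: bool


@dataclass(frozen=True)
class DriftEstimate:
    rate_pct_per_cycle: float  # 100*(e^slope - 1); negative = variance loss
    se_pct: float


@dataclass
class FactorAnalysisResult:
    generation: int
    grand_mean: float
    level_means: dict  # factor -> {level: mean}
    tukey: dict  # factor -> DataFrame of pairwise comparisons
    letters: dict  # factor -> {level: letter string}
    alpha: float = 0.05


def cycles_to_depletion(
    variance: np.ndarray, threshold: float = 0.80
) -> DepletionResult:
    """First cycle at which variance has lost ``threshold`` of its initial value.

    ``variance`` is the replicate-mean trajectory starting at cycle 0.
    Censored when the trajectory never crosses.
    """
    v = np.asarray(variance, dtype=float)
    if len(v) < 1 or v[0] <= 0:
        raise ValueError("trajectory must start at cycle 0 with positive variance")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    target = (1.0 - threshold) * v[0]
    hits = np.flatnonzero(v <= target)
    if hits.size == 0:
        return DepletionResult(threshold=threshold, cycle=None, censored=True)
    return DepletionResult(threshold=threshold, cycle=int(hits[0]), censored=False)


def drift_rate(variance: np.ndarray) -> DriftEstimate:
    """Per-cycle percent change of genetic variance, log-linear fit.

    Intended for random-selection trajectories, where change is pure
    drift. The slope of ln(variance) on cycle maps to a percent rate via
    100*(e^slope - 1); the standard error follows by the delta method.
    """
    v = np.asarray(variance, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 cycles")
    if np.any(v <= 0):
        raise ValueError("variance must be positive throughout")
    cycles = np.arange(len(v), dtype=float)
    fit = stats.linregress(cycles, np.log(v))
    rate = 100.0 * (np.exp(fit.slope) - 1.0)
    se = 100.0 * np.exp(fit.slope) * fit.stderr
    return DriftEstimate(rate_pct_per_cycle=float(rate), se_pct=float(se))


def _letter_groups(levels, pmat, alpha):
    """Compact letter display from a pairwise p-value matrix.

    Levels must be ordered by descending mean. Maximal runs of mutually
    non-significant levels share a letter.
    """
    k = len(levels)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and np.all(pmat[i : j + 2, i : j + 2][np.triu_indices(j + 2 - i, 1)] > alpha):
            j += 1
        intervals.append((i, j))
    # drop intervals nested in another
    maximal = [
        (a, b)
        for a, b in intervals
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    maximal = sorted(set(maximal))
    letters = {lv: "" for lv in levels}
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for i in range(a, b + 1):
            letters[levels[i]] += ch
    return letters


def factor_analysis(
    results: pd.DataFrame,
    generation: int,
    response: str = "mean_tbv",
    alpha: float = 0.05,
) -> FactorAnalysisResult:
    """Additive fixed-effects evaluation of the simulation factors.

    Fits ``response ~ model + strategy + intensity + design`` on the
    replicate-level scenario means at the given generation (factors with a
    single level are dropped with a warning), then performs Tukey-Kramer
    pairwise comparisons within each factor using the additive model's
    residual mean square, and summarises each factor's levels with compact
    letters: levels sharing a letter are not significantly different.
    """
    df = results[results["cycle"] == generation].copy()
    if df.empty:
        raise ValueError(f"no rows at generation {generation}")
    df["intensity"] = df["intensity"].astype(str)
    factors = [f for f in FACTORS if f in df and df[f].nunique() >= 2]
    dropped = [f for f in FACTORS if f in df and df[f].nunique() < 2]
    if dropped:
        warnings.warn(f"single-level factors dropped: {dropped}")
    if not factors:
        raise ValueError("need at least one factor with two or more levels")

    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=df).fit()
    mse = float(fit.mse_resid)
    dfr = int(fit.df_resid)

    level_means, tukey_tables, letters = {}, {}, {}
    for f in factors:
        # deterministic ordering: descending mean, ties by level name
        g = df.groupby(f)[response].agg(["mean", "count"]).sort_index()
        g = g.sort_values("mean", ascending=False, kind="stable")
        levels = list(g.index)
        k = len(levels)
        pmat = np.ones((k, k))
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                mi, ni = g["mean"].iloc[i], g["count"].iloc[i]
                mj, nj = g["mean"].iloc[j], g["count"].iloc[j]
                se = np.sqrt(mse / 2.0 * (1.0 / ni + 1.0 / nj))
                q = abs(mi - mj) / se if se > 0 else np.inf
                p = float(stats.studentized_range.sf(q, k, dfr))
                pmat[i, j] = pmat[j, i] = p
                rows.append(
                    {"level_a": levels[i], "level_b": levels[j],
                     "diff": mi - mj, "p_adj": p, "significant": p < alpha}
                )
        level_means[f] = dict(g["mean"])
        tukey_tables[f] = pd.DataFrame(rows)
        letters[f] = _letter_groups(levels, pmat, alpha)

    return FactorAnalysisResult(
        generation=generation,
        grand_mean=float(df[response].mean()),
        level_means=level_means,
        tukey=tukey_tables,
        letters=letters,
        alpha=alpha,
    )
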