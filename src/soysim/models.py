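"""Candidate scoring: truth, random, phenotype, whole-genome regression, RF.

The linear genomic models share the form y = Xb + M beta (+ gamma for the
variable-selection variant) + e, with the environment (breeding cycle)
as a fixed effect, and differ only in the prior on marker effects:

* GBLUP / ridge — one common normal variance across markers;
* BayesA — per-marker scaled-inverse-chi-square (Student-t marginal);
* BayesB — BayesA plus a spike-and-slab inclusion indicator gamma;
* FLM — double-exponential (Laplace) prior, an empirical-Bayes LASSO.

All four are solved by expectation-maximisation with Gauss-Seidel
coordinate updates; random forest is the one non-linear alternative.
Training uses a sliding window over the most recent completed cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._kernels import em_wgr_kernel
from .genome import Population

__all__ = [
    "TrainingSet",
    "PredictionModel",
    "WGR_METHODS",
    "SCORE_MODES",
    "assemble_training_window",
    "fit_wgr",
    "fit_rf",
    "score_candidates",
    "prediction_accuracy",
]

WGR_METHODS = {"GBLUP": 0, "BayesA": 1, "BayesB": 2, "FLM": 3}
SCORE_MODES = ("TBV", "Random", "Pheno", "GBLUP", "BayesA", "BayesB", "FLM", "RF")


@dataclass
class TrainingSet:
    """Aligned marker dosages, phenotypes, and cycle labels."""

    M: np.ndarray  # (n, m) dosages
    y: np.ndarray  # (n,)
    cycle: np.ndarray  # (n,) environment label per record

    def __post_init__(self):
        if not (len(self.M) == len(self.y) == len(self.cycle)):
            raise ValueError("M, y and cycle must be row-aligned")

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class PredictionModel:
    """Fitted state of one scoring method."""

    method: str
    beta: np.ndarray | None = None  # marker effects (centred parameterisation)
    gamma: np.ndarray | None = None  # inclusion indicators (BayesB; ones otherwise)
    b: np.ndarray | None = None  # environment means per training cycle
    col_means: np.ndarray | None = None  # training marker means used for centring
    sigma_e: float | None = None
    n_iter: int = 0
    converged: bool = True
    ensemble: RandomForestRegressor | None = None
    y_offset: float = 0.0  # mean environment effect added back by RF predictions

    def predict(self, M: np.ndarray) -> np.ndarray:
        """Estimated genetic merit of candidates from their marker dosages."""
        if self.ensemble is not None:
            return self.ensemble.predict(M) + self.y_offset
        if self.beta is None:
            raise ValueError("model has no fitted state")
        Xc = M.astype(np.float64) - self.col_means
        return float(np.mean(self.b)) + Xc @ (self.beta * self.gamma)

    def dump(self, path) -> None:
        """Audit sidecar: effects, environment means, and convergence info."""
        import json

        payload = {
            "method": self.method,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "sigma_e": self.sigma_e,
            "b": None if self.b is None else list(map(float, self.b)),
            "beta": None if self.beta is None else list(map(float, self.beta)),
            "gamma": None if self.gamma is None else list(map(float, self.gamma)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def assemble_training_window(
    history: list[tuple[int, np.ndarray, np.ndarray]],
    window: int = 3,
    max_records: int = 45_000,
) -> TrainingSet:
    """Concatenate the most recent ``window`` completed cycles' records.

    ``history`` is a per-cycle archive of (cycle, marker matrix, phenotypes),
    oldest first, excluding the current cycle's candidates. The record count
    is capped at ``max_records``, dropping oldest rows first.
    """
    if not history:
        raise ValueError("empty history: no completed cycles to train on")
    recent = history[-window:]
    M = np.concatenate([h[1] for h in recent], axis=0)
    y = np.concatenate([h[2] for h in recent])
    cyc = np.concatenate([np.full(len(h[2]), h[0], dtype=np.int64) for h in recent])
    if len(y) > max_records:
        M, y, cyc = M[-max_records:], y[-max_records:], cyc[-max_records:]
    return TrainingSet(M=M, y=y, cycle=cyc)


def fit_wgr(
    method: str,
    ts: TrainingSet,
    hyperparams: dict | None = None,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> PredictionModel:
    """EM-solved whole-genome regression.

    Iterates (a) Gauss-Seidel solution of the penalised system for the
    environment means and marker effects given per-marker penalties
    lambda_j = sigma_e^2 / sigma_beta_j^2, (b) prior-specific updates of
    the marker-effect variances, and (c) a residual-variance update; stops
    when max|change in effect| < ``tol``. Hyperparameters (all optional):
    ``nu`` (t prior df, default 4), ``S2`` (t prior scale; derived from
    ``r2_init`` when absent), ``pi_in`` (BayesB inclusion prior, 0.5),
    ``r2_init`` (initial marker-explained variance fraction, 0.5), and
    ``fixed_lambda`` (freeze a common ridge penalty; variance updates are
    then skipped, giving the exact ridge solution).
    """
    if method not in WGR_METHODS:
        raise ValueError(f"unknown WGR method {method!r}")
    if ts.n_records == 0:
        raise ValueError("empty training set")
    hp = dict(nu=4.0, S2=None, pi_in=0.5, r2_init=0.5, fixed_lambda=None)
    hp.update(hyperparams or {})

    uniq, group = np.unique(ts.cycle, return_inverse=True)
    M = ts.M.astype(np.float64)
    col_means = M.mean(axis=0)
    Xt = np.ascontiguousarray((M - col_means).T)
    y = ts.y.astype(np.float64)
    m = Xt.shape[0]

    vy = y.var()
    msx = float(np.sum(Xt * Xt) / len(y))
    if vy <= 0 or msx <= 0:
        # constant response or fully fixed markers (e.g. variance exhausted
        # late in a closed programme): nothing to regress on
        warnings.warn("degenerate training set: returning intercept-only model")
        return PredictionModel(
            method=method,
            beta=np.zeros(m),
            gamma=np.ones(m),
            b=np.array([y[group == k].mean() for k in range(len(uniq))]),
            col_means=col_means,
            sigma_e=float(vy),
            converged=True,
        )
    vb0 = hp["r2_init"] * vy / msx
    nu = float(hp["nu"])
    S2 = float(hp["S2"]) if hp["S2"] is not None else vb0 * (nu - 2.0) / nu
    lam_fixed = float(hp["fixed_lambda"]) if hp["fixed_lambda"] is not None else -1.0

    b, beta, gamma, ve, n_iter, conv = em_wgr_kernel(
        Xt,
        y,
        group.astype(np.int64),
        len(uniq),
        WGR_METHODS[method],
        nu,
        S2,
        float(hp["pi_in"]),
        vb0,
        lam_fixed,
        tol,
        max_iter,
    )
    if not conv:
        warnings.warn(f"{method} EM did not converge in {max_iter} iterations")
    return PredictionModel(
        method=method,
        beta=beta,
        gamma=gamma if method == "BayesB" else np.ones(m),
        b=b,
        col_means=col_means,
        sigma_e=float(ve),
        n_iter=int(n_iter),
        converged=bool(conv),
    )


def fit_rf(
    ts: TrainingSet,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int | None = None,
    **tree_kwargs,
) -> PredictionModel:
    """Random forest regression on the marker dosages.

    Defaults mirror the common tool defaults: 500 trees and
    mtry = floor(sqrt(n_markers)). The environment effect is absorbed by
    centring the response within training cycle; predictions add back the
    mean cycle effect.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if ts.n_records == 0:
        raise ValueError("empty training set")
    uniq, group = np.unique(ts.cycle, return_inverse=True)
    cyc_means = np.array([ts.y[group == k].mean() for k in range(len(uniq))])
    y_cen = ts.y - cyc_means[group]
    m = ts.M.shape[1]
    mtry = mtry if mtry is not None else max(1, int(np.sqrt(m)))
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(mtry, m),
        random_state=None if seed is None else int(seed),
        n_jobs=1,
        **tree_kwargs,
    )
    rf.fit(ts.M, y_cen)
    return PredictionModel(
        method="RF", ensemble=rf, y_offset=float(cyc_means.mean()), converged=True
    )


def score_candidates(
    mode: str,
    candidates: Population,
    model: PredictionModel | None = None,
    rng: np.random.Generator | None = None,
    M: np.ndarray | None = None,
) -> np.ndarray:
    """Selection score per candidate under the requested mode.

    TBV uses the truth, Random draws i.i.d. uniforms, Pheno returns the
    candidates' own phenotypes, and the genomic modes apply the fitted
    model to the candidates' marker dosages ``M``.
    """
    if mode not in SCORE_MODES:
        raise ValueError(f"unknown scoring mode {mode!r}")
    if mode == "TBV":
        if candidates.tbv is None:
            raise ValueError("TBVs not computed")
        return candidates.tbv.copy()
    if mode == "Random":
        rng = rng or np.random.default_rng()
        return rng.uniform(size=candidates.n_individuals)
    if mode == "Pheno":
        if candidates.phenotype is None:
            raise ValueError("candidates have no phenotypes")
        return candidates.phenotype.copy()
    if model is None:
        raise ValueError(f"mode {mode!r} requires a fitted model")
    if M is None:
        raise ValueError("genomic modes require the candidates' marker matrix M")
    return model.predict(M)


def prediction_accuracy(scores: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between scores and true breeding values.

    Returns NaN when either vector is constant (undefined correlation).
    """
    scores = np.asarray(scores, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if len(scores) != len(tbv) or len(scores) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if scores.std() == 0 or tbv.std() == 0:
        return float("nan")
    return float(np.corrcoef(scores, tbv)[0, 1])
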