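"""Truncation selection: across families, within families, and within
pre-selected families.

All three operate on a score vector (whatever the scoring mode produced)
and return selected individual ids. Ties are broken by ascending id so
every strategy is reproducible. Quotas use round-half-up with a floor of
one individual, so the effective intensity can differ slightly from the
nominal one at small family sizes (e.g. 2.5% of 50 -> 1 per family).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["select_af", "select_wf", "select_wpsf", "round_half_up", "audit_table"]


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _check(scores, ids):
    scores = np.asarray(scores, dtype=float)
    ids = np.arange(len(scores)) if ids is None else np.asarray(ids)
    if len(ids) != len(scores):
        raise ValueError("scores and ids must align")
    return scores, ids


def _top_by_score(scores, ids, k):
    order = np.lexsort((ids, -scores))
    return ids[order[:k]]


def select_af(scores, n_select: int, ids=None) -> np.ndarray:
    """Across-family selection: the n_select highest scores, family-blind."""
    scores, ids = _check(scores, ids)
    if not 1 <= n_select <= len(scores):
        raise ValueError("n_select must be in [1, population size]")
    return _top_by_score(scores, ids, n_select)


def select_wf(scores, family_ids, intensity: float, ids=None) -> np.ndarray:
    """Within-family selection: every family contributes a quota.

    ``intensity`` is a fraction in (0, 1]; per-family quota is
    max(1, round(intensity * family size)), so all families stay
    represented among the parents.
    """
    scores, ids = _check(scores, ids)
    if not 0 < intensity <= 1:
        raise ValueError("intensity must be a fraction in (0, 1]")
    family_ids = np.asarray(family_ids)
    selected = []
    for fam in np.unique(family_ids):
        mask = family_ids == fam
        size = int(mask.sum())
        if size == 0:  # pragma: no cover - unique() never yields empty groups
            warnings.warn(f"family {fam} is empty; skipped")
            continue
        q = min(max(1, round_half_up(intensity * size)), size)
        selected.append(_top_by_score(scores[mask], ids[mask], q))
    return np.concatenate(selected)


def select_wpsf(
    scores, family_ids, intensity: float, family_fraction: float = 0.30, ids=None
) -> np.ndarray:
    """Two-stage selection: keep the best families, then select within them.

    Families are ranked by mean candidate score and the top
    ``ceil(family_fraction * n_families)`` kept; the population-level
    target N = round(intensity * population size) is split into equal
    per-family quotas max(1, round(N / n_kept)) among the kept families.
    """
    scores, ids = _check(scores, ids)
    if not 0 < intensity <= 1:
        raise ValueError("intensity must be a fraction in (0, 1]")
    if not 0 < family_fraction <= 1:
        raise ValueError("family_fraction must be in (0, 1]")
    family_ids = np.asarray(family_ids)
    fams = np.unique(family_ids)
    n_keep = int(np.ceil(family_fraction * len(fams)))
    if n_keep < 1:
        raise ValueError("family_fraction keeps no family")
    fam_means = np.array([scores[family_ids == f].mean() for f in fams])
    order = np.lexsort((fams, -fam_means))
    kept = fams[order[:n_keep]]

    target = max(1, round_half_up(intensity * len(scores)))
    quota = max(1, round_half_up(target / n_keep))
    selected = []
    for fam in kept:
        mask = family_ids == fam
        q = min(quota, int(mask.sum()))
        selected.append(_top_by_score(scores[mask], ids[mask], q))
    return np.concatenate(selected)


def audit_table(scores, family_ids, selected_ids, ids=None, cycle=0,
                strategy="", intensity=float("nan")):
    """Per-candidate audit record of one selection round (for CSV export)."""
    import pandas as pd

    scores, ids = _check(scores, ids)
    return pd.DataFrame(
        {
            "cycle": cycle,
            "strategy": strategy,
            "intensity": intensity,
            "family": np.asarray(family_ids),
            "id": ids,
            "score": scores,
            "selected": np.isin(ids, selected_ids),
        }
    )
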