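"""Meiosis, biparental crossing, single-seed-descent inbreeding, pairing.

Recombination follows a no-interference model: per chromosome the
crossover count is Poisson with mean equal to the map length in Morgans
and crossover positions are uniform in cM, which implies Haldane's map
function for the recombination fraction between any two sites. There is
no mutation after the founder generation — the programme is closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import gamete_kernel
from .genome import GeneticMap, Population

__all__ = [
    "CrossPlan",
    "meiosis",
    "make_crosses",
    "ssd_advance",
    "pair_parents",
]


@dataclass(frozen=True)
class CrossPlan:
    """Ordered biparental crosses; one F1 seed per pair at defaults."""

    pairs: np.ndarray  # (n_crosses, 2) parent ids

    def __post_init__(self):
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be (n, 2)")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pairings are not allowed")

    @property
    def n_crosses(self) -> int:
        return len(self.pairs)


def _gamete_batch(
    haps: np.ndarray, parent_idx: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """All randomness drawn vectorised up front, assembly in the jit kernel."""
    G = len(parent_idx)
    n_chr = gmap.n_chromosomes
    lengths = gmap.lengths_cm
    counts = rng.poisson(lengths / 100.0, size=(G, n_chr))
    total = int(counts.sum())
    u = rng.random(total)
    # sort crossover positions within each (gamete, chromosome) segment via a
    # single global sort keyed on segment id + fractional position
    seg_id = np.repeat(np.arange(G * n_chr, dtype=np.float64), counts.ravel())
    sv = np.sort(seg_id + u)
    frac = sv - np.floor(sv)
    chr_of = (np.floor(sv).astype(np.int64)) % n_chr
    xo_pos = frac * lengths[chr_of]
    xo_offsets = np.concatenate([[0], np.cumsum(counts.ravel())]).astype(np.int64)
    start_parity = rng.integers(0, 2, size=(G, n_chr), dtype=np.uint8)

    out = np.empty((G, gmap.total_sites), dtype=np.uint8)
    gamete_kernel(
        haps,
        parent_idx.astype(np.int64),
        start_parity,
        xo_pos,
        xo_offsets,
        gmap.chrom_offsets.astype(np.int64),
        gmap.site_pos,
        out,
    )
    return out


def meiosis(
    haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a single phased individual ``(2, S)`` -> ``(S,)``."""
    if haplotypes.shape != (2, gmap.total_sites):
        raise ValueError("haplotypes do not match the map")
    return _gamete_batch(
        haplotypes[None, :, :], np.zeros(1, dtype=np.int64), gmap, rng
    )[0]


def make_crosses(
    pop: Population, plan: CrossPlan, rng: np.random.Generator
) -> Population:
    """Produce one F1 individual per planned cross (union of two gametes)."""
    id_to_idx = {int(i): k for k, i in enumerate(pop.ids)}
    try:
        idx_a = np.array([id_to_idx[int(a)] for a in plan.pairs[:, 0]], dtype=np.int64)
        idx_b = np.array([id_to_idx[int(b)] for b in plan.pairs[:, 1]], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"parent id {e.args[0]} not in population") from None
    gam_a = _gamete_batch(pop.haplotypes, idx_a, pop.gmap, rng)
    gam_b = _gamete_batch(pop.haplotypes, idx_b, pop.gmap, rng)
    haps = np.stack([gam_a, gam_b], axis=1)
    n = plan.n_crosses
    return Population(
        haplotypes=haps,
        gmap=pop.gmap,
        ids=np.arange(n, dtype=np.int64),
        family=np.arange(n, dtype=np.int64),
        generation="F1",
        cycle=pop.cycle,
    )


def _self_batch(
    haps: np.ndarray, parent_idx: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    a = _gamete_batch(haps, parent_idx, gmap, rng)
    b = _gamete_batch(haps, parent_idx, gmap, rng)
    return np.stack([a, b], axis=1)


def ssd_advance(
    f1: Population,
    family_size: int,
    n_selfing_rounds: int = 2,
    gmap: GeneticMap | None = None,
    rng: np.random.Generator | None = None,
) -> Population:
    """Single seed descent: F1 -> family_size F2 lines -> F(2+rounds).

    The F1 of each family is selfed to create ``family_size`` F2
    individuals; each F2 line is then advanced by ``n_selfing_rounds``
    rounds of selfing keeping a single descendant per round (2 rounds at
    defaults, yielding F2:4 lines tagged F4).
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if n_selfing_rounds < 0:
        raise ValueError("n_selfing_rounds must be >= 0")
    gmap = gmap or f1.gmap
    rng = rng or np.random.default_rng()
    n_fam = f1.n_individuals
    parent_idx = np.repeat(np.arange(n_fam, dtype=np.int64), family_size)
    cur = _self_batch(f1.haplotypes, parent_idx, gmap, rng)  # F2
    n = cur.shape[0]
    everyone = np.arange(n, dtype=np.int64)
    for _ in range(n_selfing_rounds):
        cur = _self_batch(cur, everyone, gmap, rng)
    return Population(
        haplotypes=cur,
        gmap=gmap,
        ids=np.arange(n, dtype=np.int64),
        family=f1.family[parent_idx],
        generation=f"F{2 + n_selfing_rounds}",
        cycle=f1.cycle,
    )


def pair_parents(
    selected_ids: np.ndarray, n_crosses: int, rng: np.random.Generator
) -> CrossPlan:
    """Draw random biparental pairs from the selected parents.

    Pairs are uniform over distinct ordered pairs; individuals may repeat
    across crosses and some selected parents may go unused.
    """
    ids = np.asarray(selected_ids)
    k = len(ids)
    if k < 2:
        raise ValueError("need at least 2 selected individuals")
    if n_crosses < 1:
        raise ValueError("n_crosses must be >= 1")
    a = rng.integers(0, k, size=n_crosses)
    b = rng.integers(0, k - 1, size=n_crosses)
    b = b + (b >= a)  # uniform over the k-1 partners distinct from a
    return CrossPlan(pairs=np.stack([ids[a], ids[b]], axis=1))
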