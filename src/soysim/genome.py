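"""Genetic map, founder haplotypes, and SNP-array marker panel.

The simulated genome emulates soybean: 20 chromosomes averaging 115 cM,
jointly spanning 950 Mb, with 1,000 segregating biallelic sites per
chromosome in the default configuration. Founders are drawn from a
coalescent-with-recombination model so that allele frequencies and
linkage disequilibrium have a realistic population-genetic structure;
a ~6K marker panel mimicking a commercial SNP array is then chosen from
the segregating sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import msprime
import numpy as np

__all__ = [
    "GeneticMap",
    "Population",
    "MarkerPanel",
    "HistoryParams",
    "build_genetic_map",
    "simulate_founders",
    "select_marker_panel",
    "genotype_matrix",
]

#: recombination rate in crossovers per cM (1 cM == 1% recombination)
RECOMB_PER_CM = 0.01


@dataclass(frozen=True)
class GeneticMap:
    """Chromosome structure and site coordinates.

    Sites live at floating-point positions in centimorgans, strictly inside
    ``[0, length)`` of their chromosome and sorted ascending. Physical spans
    in bp are bookkeeping only (used for VCF export); all genetics happens
    in map distance.
    """

    lengths_cm: np.ndarray  # (n_chr,) chromosome map lengths, cM
    spans_bp: np.ndarray  # (n_chr,) physical spans, bp
    site_chrom: np.ndarray  # (S,) chromosome index of each site
    site_pos: np.ndarray  # (S,) position in cM within chromosome

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths_cm)

    @property
    def total_sites(self) -> int:
        return len(self.site_pos)

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Start index of each chromosome's site block, plus terminal S."""
        counts = np.bincount(self.site_chrom, minlength=self.n_chromosomes)
        return np.concatenate([[0], np.cumsum(counts)])

    def sites_of(self, chrom: int) -> np.ndarray:
        off = self.chrom_offsets
        return self.site_pos[off[chrom] : off[chrom + 1]]

    def __post_init__(self):
        if np.any(self.lengths_cm <= 0):
            raise ValueError("chromosome lengths must be positive")
        off = self.chrom_offsets
        for c in range(self.n_chromosomes):
            pos = self.site_pos[off[c] : off[c + 1]]
            if pos.size and (pos.min() < 0 or pos.max() >= self.lengths_cm[c]):
                raise ValueError("site positions outside chromosome bounds")
            if np.any(np.diff(pos) < 0):
                raise ValueError("site positions must be sorted within chromosome")


@dataclass
class Population:
    """A set of diploid individuals on a shared genetic map.

    Haplotypes are stored as a dense ``(n, 2, S)`` uint8 array of 0/1
    alleles — phased, one row of two haplotypes per individual, sites in
    map order across all chromosomes.
    """

    haplotypes: np.ndarray
    gmap: GeneticMap
    ids: np.ndarray
    family: np.ndarray
    generation: str
    cycle: int = 0
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None
    gxe: np.ndarray | None = None
    residual: np.ndarray | None = None

    def __post_init__(self):
        n = self.haplotypes.shape[0]
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, S)")
        if self.haplotypes.shape[2] != self.gmap.total_sites:
            raise ValueError("haplotype length does not match map site count")
        if len(self.ids) != n or len(self.family) != n:
            raise ValueError("ids/family must match individual count")
        if len(np.unique(self.ids)) != n:
            raise ValueError("individual ids must be unique within a cycle")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def dosage(self, site_indices: np.ndarray | None = None) -> np.ndarray:
        """Allele dosage in {0,1,2}; optionally restricted to given sites."""
        h = self.haplotypes
        if site_indices is not None:
            h = h[:, :, site_indices]
        return h.sum(axis=1, dtype=np.int8)

    def mean_heterozygosity(self) -> float:
        return float((self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean())

    def subset(self, indices: np.ndarray) -> "Population":
        def _take(a):
            return None if a is None else a[indices]

        return Population(
            haplotypes=self.haplotypes[indices],
            gmap=self.gmap,
            ids=self.ids[indices],
            family=self.family[indices],
            generation=self.generation,
            cycle=self.cycle,
            tbv=_take(self.tbv),
            phenotype=_take(self.phenotype),
            gxe=_take(self.gxe),
            residual=_take(self.residual),
        )


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered subset of map sites genotyped by the array."""

    site_indices: np.ndarray  # flat indices into the map's site arrays, sorted

    @property
    def n_markers(self) -> int:
        return len(self.site_indices)

    def pairs(self, gmap: GeneticMap) -> list[tuple[int, int]]:
        """(chromosome, site-index-within-chromosome) pairs."""
        off = gmap.chrom_offsets
        chroms = gmap.site_chrom[self.site_indices]
        return [(int(c), int(i - off[c])) for c, i in zip(chroms, self.site_indices)]


@dataclass(frozen=True)
class HistoryParams:
    """Demographic history behind the founder coalescent.

    ne
        Diploid effective population size of the ancestral pool. Small
        values give the strong LD and drifted frequency spectrum typical
        of an elite self-pollinating crop programme.
    """

    ne: float = 100.0


def build_genetic_map(
    n_chr: int = 20,
    mean_length_cm: float = 115.0,
    sites_per_chr: int = 1000,
    total_bp: int = 950_000_000,
    seed: int | None = None,
    jitter_cm: float = 10.0,
) -> GeneticMap:
    """Construct a genetic map with jittered chromosome lengths.

    Lengths are drawn uniformly within ``mean ± jitter`` then rescaled so the
    mean is exactly ``mean_length_cm``; physical spans are proportional to map
    lengths and sum to ``total_bp``. Site positions are uniform within each
    chromosome and sorted. Deterministic given ``seed``.
    """
    if n_chr < 1 or sites_per_chr < 1 or total_bp < 1:
        raise ValueError("n_chr, sites_per_chr and total_bp must be positive")
    if mean_length_cm <= 0:
        raise ValueError("mean_length_cm must be positive")
    rng = np.random.default_rng(seed)
    jitter = min(jitter_cm, 0.9 * mean_length_cm)
    lengths = mean_length_cm + rng.uniform(-jitter, jitter, size=n_chr)
    lengths *= mean_length_cm / lengths.mean()
    spans = np.floor(total_bp * lengths / lengths.sum()).astype(np.int64)
    spans[-1] += total_bp - spans.sum()

    chroms, positions = [], []
    for c in range(n_chr):
        pos = np.sort(rng.uniform(0.0, lengths[c], size=sites_per_chr))
        # dedupe pathological collisions (measure zero, but required downstream)
        while len(np.unique(pos)) != len(pos):  # pragma: no cover
            pos = np.sort(rng.uniform(0.0, lengths[c], size=sites_per_chr))
        positions.append(pos)
        chroms.append(np.full(sites_per_chr, c, dtype=np.int32))
    return GeneticMap(
        lengths_cm=lengths,
        spans_bp=spans,
        site_chrom=np.concatenate(chroms),
        site_pos=np.concatenate(positions),
    )


def _drop_site_mutations(ts, positions: np.ndarray, rng: np.random.Generator):
    """Place one mutation per requested position, edge chosen ∝ branch length.

    Equivalent to conditioning an infinite-sites model on exactly one hit at
    the site; every non-root edge subtends a proper subset of samples, so the
    site is guaranteed to segregate.
    """
    times = ts.tables.nodes.time
    chosen_nodes = np.empty(len(positions), dtype=np.int64)
    i = 0
    for tree in ts.trees():
        left, right = tree.interval
        while i < len(positions) and left <= positions[i] < right:
            order = tree.preorder()
            parents = tree.parent_array[order]
            valid = parents >= 0
            nodes = order[valid]
            bl = times[parents[valid]] - times[nodes]
            chosen_nodes[i] = nodes[rng.choice(len(nodes), p=bl / bl.sum())]
            i += 1
        if i == len(positions):
            break
    tables = ts.dump_tables()
    tables.sites.clear()
    tables.mutations.clear()
    for pos, node in zip(positions, chosen_nodes):
        sid = tables.sites.add_row(position=pos, ancestral_state="0")
        tables.mutations.add_row(site=sid, node=int(node), derived_state="1")
    tables.sort()
    return tables.tree_sequence()


def simulate_founders(
    gmap: GeneticMap,
    n_founders: int = 200,
    history: HistoryParams | None = None,
    seed: int | None = None,
    max_retries: int = 3,
) -> Population:
    """Simulate founder haplotypes under a coalescent with recombination.

    Each chromosome is simulated in cM coordinates (recombination rate
    0.01 per cM) at diploid size ``history.ne``; one biallelic variant is
    then placed at every map site by branch-weighted mutation dropping.
    The result is a fully phased founder population in which every site
    segregates and LD decays with map distance.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    history = history or HistoryParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_chr = gmap.n_chromosomes
    child_seeds = ss.spawn(2 * n_chr)

    hap = np.empty((n_founders, 2, gmap.total_sites), dtype=np.uint8)
    off = gmap.chrom_offsets
    for c in range(n_chr):
        positions = gmap.sites_of(c)
        msp_seed = int(child_seeds[2 * c].generate_state(1)[0] % (2**31 - 1)) + 1
        rng = np.random.default_rng(child_seeds[2 * c + 1])
        for attempt in range(max_retries):
            ts = msprime.sim_ancestry(
                samples=n_founders,
                ploidy=2,
                population_size=history.ne,
                sequence_length=float(gmap.lengths_cm[c]),
                recombination_rate=RECOMB_PER_CM,
                discrete_genome=False,
                random_seed=msp_seed + attempt,
            )
            ts = _drop_site_mutations(ts, positions, rng)
            G = ts.genotype_matrix()  # (sites, 2n)
            counts = G.sum(axis=1)
            if np.all((counts > 0) & (counts < 2 * n_founders)):
                break
        else:  # pragma: no cover - branch dropping cannot produce fixed sites
            raise RuntimeError(f"non-segregating site on chromosome {c}")
        block = G.T.astype(np.uint8)  # (2n, sites)
        hap[:, 0, off[c] : off[c + 1]] = block[0::2]
        hap[:, 1, off[c] : off[c + 1]] = block[1::2]

    return Population(
        haplotypes=hap,
        gmap=gmap,
        ids=np.arange(n_founders, dtype=np.int64),
        family=np.full(n_founders, -1, dtype=np.int64),
        generation="founder",
        cycle=0,
    )


def _founder_maf(founders: Population) -> np.ndarray:
    p = founders.haplotypes.mean(axis=(0, 1))
    return np.minimum(p, 1.0 - p)


def select_marker_panel(
    founders: Population, gmap: GeneticMap, n_markers: int = 6000
) -> MarkerPanel:
    """Choose an array-like marker panel from the segregating sites.

    Chromosomes contribute equal quotas. Within a chromosome the map is
    split into quota-many equal-cM bins and the site with the highest
    founder minor-allele frequency in each bin is taken (even spacing +
    informativeness, as commercial arrays are designed); empty-bin
    deficits are filled with the remaining highest-MAF sites of that
    chromosome. Deterministic given the founders.
    """
    S = gmap.total_sites
    if n_markers < 1 or n_markers > S:
        raise ValueError("n_markers must be in [1, total sites]")
    if n_markers == S:
        return MarkerPanel(site_indices=np.arange(S, dtype=np.int64))

    maf = _founder_maf(founders)
    n_chr = gmap.n_chromosomes
    quota = np.full(n_chr, n_markers // n_chr, dtype=np.int64)
    quota[: n_markers % n_chr] += 1

    off = gmap.chrom_offsets
    chosen: list[int] = []
    for c in range(n_chr):
        q = int(min(quota[c], off[c + 1] - off[c]))
        if q == 0:
            continue
        pos = gmap.sites_of(c)
        m = maf[off[c] : off[c + 1]]
        bins = np.minimum((pos / gmap.lengths_cm[c] * q).astype(np.int64), q - 1)
        picked: list[int] = []
        for b in range(q):
            in_bin = np.flatnonzero(bins == b)
            if in_bin.size:
                best = in_bin[np.argmax(m[in_bin])]
                picked.append(int(best))
        # top up empty-bin deficit with best remaining sites
        if len(picked) < q:
            remaining = np.setdiff1d(np.arange(len(pos)), np.array(picked, dtype=int))
            order = remaining[np.argsort(-m[remaining], kind="stable")]
            picked.extend(int(i) for i in order[: q - len(picked)])
        chosen.extend(int(off[c] + i) for i in picked)
    idx = np.unique(np.array(chosen, dtype=np.int64))
    return MarkerPanel(site_indices=idx)


def genotype_matrix(pop: Population, panel: MarkerPanel) -> np.ndarray:
    """Dosage matrix for the panel: rows = individuals, entries in {0,1,2}."""
    if pop.n_individuals == 0:
        raise ValueError("empty population")
    if panel.site_indices.max(initial=-1) >= pop.gmap.total_sites:
        raise ValueError("panel site outside the population's map")
    return pop.dosage(panel.site_indices)
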