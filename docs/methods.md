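# Methods

`soysim` simulates a closed soybean breeding programme — no germplasm enters
after the founder generation — and measures how the prediction model, the
breeding strategy, the selection intensity, and the family structure shape
long-term genetic gain and the erosion of additive genetic variance.

## Genome and founders

The genome is 20 chromosomes averaging 115 cM (uniform ±10 cM jitter,
rescaled so the mean is exact), spanning 950 Mb in total, with 1,000
segregating biallelic sites placed uniformly per chromosome. Physical
coordinates are bookkeeping only (used by the VCF export); all genetics is
computed in map distance.

Founder haplotypes come from a coalescent with recombination (msprime), run
per chromosome in cM coordinates with recombination rate 0.01/cM at a
diploid effective size of Ne = 100 (config-exposed). The small Ne gives the
strong linkage disequilibrium and drifted allele-frequency spectrum expected
of an elite self-pollinating crop pool; LD decays with map distance by
construction. One variant is placed at every map site by choosing an edge of
the local tree with probability proportional to branch length — the
infinite-sites distribution conditional on exactly one mutation — which
guarantees every site segregates in the founders. After the founders, no
mutation occurs: the programme is closed, and erosion reflects selection and
drift only.

The marker panel (default 6,000, emulating a mid-density SNP array) takes an
equal quota per chromosome; within a chromosome the map is cut into
quota-many equal-cM bins and the highest-founder-MAF site per bin is chosen
(even spacing plus informativeness, as commercial arrays are designed), with
empty-bin deficits topped up by the remaining highest-MAF sites. Marker
status is independent of QTL status.

## Trait model

Grain yield (t/ha) is additive: 70% of all sites, drawn genome-wide, carry
N(0,1) effects that are rescaled by a single factor so the founder
population's TBV variance equals sigma_a^2 = 25 exactly; an intercept anchors
the founder mean at 3.00 t/ha. Phenotypes are

    y = TBV + gxe + e,  gxe ~ N(0, 49),  e ~ N(0, 121),

with the seasonal (GxE) deviate redrawn independently per individual per
season — the simplest structure consistent with a non-heritable seasonal
effect — and the residual variance held constant across cycles, so realized
heritability (~25/195 ≈ 0.128 in the founders) declines as genetic variance
is consumed. Each F4 line is phenotyped once, unreplicated, matching
early-generation trial practice. The components are stored alongside y, so
the decomposition is exactly recoverable in simulation.

The nominal units are taken at face value: a mean of 3.00 t/ha alongside a
variance of 25 (t/ha)^2 is dimensionally tense, but both numbers are treated
as being on one common simulation scale.

## Breeding cycle

Each cycle: the current parents are paired at random (distinct pairs;
individuals may repeat and some selected parents may go unused) into 300
crosses; each cross yields one F1, selfed to 50 F2 individuals; each F2 line
is advanced by single-seed descent for two more selfing rounds to F2:4
(15,000 F4 candidates per cycle at defaults). Meiosis has no crossover
interference: Poisson crossover counts with mean equal to the chromosome
length in Morgans and uniform positions, implying Haldane's map function —
testable in closed form. F1–F3 intermediates are discarded once the F4 is
formed.

## Prediction and selection

Candidates are scored by one of: true breeding value (upper bound), random
draw (lower bound), own phenotype, four EM-solved whole-genome regressions,
or random forest. The linear models share y = Xb + M·beta (+ inclusion
indicators for the spike-and-slab variant) with the training cycle as fixed
environment effect, and differ in the prior on marker effects: a common
normal variance (GBLUP/ridge), per-marker scaled-inverse-chi-square with
nu = 4 (BayesA), BayesA plus a spike-and-slab indicator with prior inclusion
probability 0.5 (BayesB), and a Laplace prior via its exponential scale
mixture with an empirical-Bayes rate refit (FLM). All are solved by
Gauss–Seidel coordinate descent inside an EM loop; the ridge path with a
frozen penalty reproduces the closed-form ridge solution to ≤1e-6, which is
the solver's correctness oracle. Convergence is max|change in effect| <
1e-8 within 300 iterations at library defaults (1e-6 / 150 in the
desk-scale experiment profile); non-convergence is flagged and the last
iterate used. Monomorphic markers keep an effect of exactly zero. GBLUP is
solved in marker space (SNP-BLUP), prediction-equivalent to
genomic-relationship BLUP, with the variance ratio re-estimated inside EM.
Random forest uses 500 trees and mtry = floor(sqrt(p)), untuned.

Training uses the previous three completed cycles (≤45,000 records, oldest
rows dropped first), never the current candidates; candidates are predicted
with the environment effect set to the mean of the training-cycle effects.
At cycle 1 there is no history, so genomic modes fall back to phenotypic
selection for that cycle (logged); genomic selection starts at cycle 2.

Selection strategies: across families (AF) takes the global top N; within
families (WF) takes max(1, round(i × family size)) per family, so every
family stays represented; within pre-selected families (WPSF) ranks families
by mean candidate score, keeps the top 30%, and splits the population-level
target equally among them. Quotas round half-up with a floor of one, so at
2.5% of 50-line families WF effectively selects 2% (1 per family); ties
break by ascending id everywhere.

## Experiment orchestration

A scenario is (model, strategy, intensity, design); the default design grid
holds n_families × family_size at 15,000 (300×50 … 100×150). Each replicate
derives its streams from SeedSequence([root, replicate, cycle]) with named
children per operation, so any cycle is reproducible in isolation and the
whole pipeline is a pure function of (config, seed). Replicate seeds do not
depend on the scenario, so grid cells share founders and all pre-selection
randomness — a common-random-numbers design that makes cross-scenario
comparisons paired and turns the TBV-upper-bound property into an exact
invariant at cycle 1. Replicates are embarrassingly parallel (joblib) and
merged in sorted order, so results are identical for any worker count.
Checkpointing is per (scenario, replicate): completed replicates are stored
as CSV and reused on resume; at most one replicate of work can be lost.

Per cycle the summary records the F4 candidate mean TBV and phenotype,
genetic variance (population variance of TBV), realized h², prediction
accuracy (Pearson correlation of scores with TBV), mean heterozygosity, and
the selected-parent count. The founder generation is recorded as cycle 0 so
variance trajectories start at their calibrated baseline.

## Erosion analysis

* **Cycles to depletion**: first cycle at which the replicate-mean genetic
  variance falls to (1 − 0.80) of its cycle-0 value; censored if never.
  Detection on the replicate-mean trajectory matches single-number-per-
  scenario reporting; a per-replicate mode is a flag away.
* **Drift rate**: slope of ln(variance) on cycle by least squares, reported
  as 100·(e^slope − 1) percent per cycle with a delta-method standard error;
  estimated only on random-selection scenarios, where change is pure drift.
  A first-differences alternative would weight early cycles more; the
  log-linear fit uses the whole trajectory and is exact on geometric decay.
* **Factor evaluation**: an additive fixed-effects OLS of replicate-level
  population means on model, strategy, intensity and design at a chosen
  generation, followed by Tukey–Kramer pairwise comparisons within each
  factor using the additive model's residual mean square, summarised as
  compact letter groupings at alpha = 0.05.

## Problem sizes and what the tests show

The full study design (15,000 individuals × 200 cycles × 60 replicates × 96
scenarios) is cluster-scale. The package's test and calibration profiles
use: 10,000–12,000 founders on a 10-chromosome × 200–300-site map for
heritability calibration (h² is invariant to site count), and a trend grid
of 50 families × 10 lines, 1,000 markers, 30 cycles, 5 replicates for the
qualitative orderings (truth-based selection bounds every other mode;
within-family selection preserves the most variance; stronger intensity
erodes variance faster; genomic selection beats random). Passing these shows
the mechanisms and their interplay are right at reduced scale; absolute
long-run numbers at the full design additionally depend on Ne, marker
density and the 200-cycle horizon and are obtained by running the full
configuration on suitable hardware.

The generator emulates allele-frequency and LD structure, Mendelian
transmission, and the stated variance components; it does not model
sequence-level realism, crossover interference, dominance/epistasis,
selection during the founder history, or correlated GxE across seasons —
conclusions about real data inherit those simplifications.
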