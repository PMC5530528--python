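# Methods

`clonebreak` jointly infers the clonal composition of a bulk tumour
whole-genome sequencing (WGS) sample and the clone-specific structure of
its genome: mixture proportions of normal cells and (up to) two tumour
clones, clone- and allele-specific integer copy numbers for genomic
segments, and clone-specific copy numbers for rearrangement breakpoints.
This note documents the model, the algorithm, the synthetic-data generator
and the numerical choices; it states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Observed data

The genome is partitioned into regular bins (default 500 kb; 0-based
half-open coordinates), with bins containing predicted breakends split so
every breakend falls on a segment boundary.  For each segment `n` the model
observes the number `x_n` of uniquely aligned, concordant read pairs fully
contained in it, allele read counts `(x_a, x_b)` aggregated from pre-phased
heterozygous-SNP haplotype blocks (assigned to segments by block midpoint),
and a bias-adjusted *effective length* — the sum of per-position weights
from a pluggable bias model (uniform, per-position array, or a GC-quantile
lookup table).  Each breakpoint `k` is a pair of oriented breakends;
orientation `o = +1` means the junction consumes extremities of the segment
left of the boundary, `o = -1` of the segment to the right.

## Model

Per-clone haploid read depths `h_m` (reads per nucleotide for one copy of a
segment in clone `m`) encode sequencing depth and mixture jointly; clone 0
is normal, fixed at one copy of each allele.  The expected total count of a
segment is

    mu_n = l_n * sum_m h_m c_nm

with `l_n` the effective length.  Total counts follow, by default, a
two-component negative binomial mixture — a low-variance bulk component
(inverse dispersion `r1 = 1000`, i.e. ~3% extra-Poisson CV at 500 kb bins)
plus a rare high-variance component (`r2 = 100`, weight 0.02) — further
mixed with a flat outlier component (weight 0.01, log-density −20 per
observation).  Poisson and single negative binomial families are available.
The allele-informative read split is beta-binomial around the expected
major-allele fraction `(h_0 + sum_m h_m c^maj_m) / (2 h_0 + sum_m h_m
c^tot_m)` with overdispersion 0.002 (~2% SD in the allele fraction for
deeply covered segments).  Because segment states are parameterised as
(major, minor) pairs, observed allele counts are folded onto the major
allele and the emission uses the two-sided (folded) density
`BB(x_maj; p) + BB(x_maj; 1 - p)`; an unfolded density on the folded counts
is biased above one half and systematically favours unbalanced states.

Adjacent segments are coupled by *telomere counts*: the number of segment
extremities a configuration leaves unconnected.  Without a breakend the
per-clone count is the absolute allele-wise copy difference; across a
breakend with orientation `o` and breakpoint copy `b_km`,

    t = |c - c' - o * b|

on the allele track carrying the junction.  The breakpoint's allele phase
is unobserved, so both tracks are scored and the minimum-telomere track
used; clones and alleles contribute additively.  Transition factors are the
un-normalised potentials `exp(-lambda * t)`; both breakends of a breakpoint
share one copy-number variable, which is what propagates copy-number
information along tumour-specific adjacencies.

The per-clone total copy number is capped at 5 (12 allele states per clone,
144 joint states for two tumour clones) and breakpoint copies at
`b_max = 2` per clone; these caps bound the chain's state space.

### The telomere penalty

`lambda` (default 4.0) controls how strongly un-explained copy-number
change is penalised.  The choice matters: with a weak penalty (~1) the
low-depth clone's copy-number track can profitably chase per-segment
emission noise, and the variational objective can even prefer a degenerate
rescaling of a clone (half the depth, double the copies) whose flatter
emissions win entropy.  Because true unbalanced rearrangements carry their
breakpoints in the chain — where the penalty is absorbed by positive `b` —
a stronger penalty suppresses spurious changes at essentially no cost to
real ones.  At `lambda = 4` the truthful basin dominates the objective in
our simulations; the value is exposed in the configuration.

## Inference

The posterior over segment copies `C`, breakpoint copies `B`, depths `h`
and likelihood parameters `theta` is approximated by the structured
factorisation `q(h) q(theta) q(C) prod_k q_k(b_k)`, with `q(h)`, `q(theta)`
delta functions (point estimates) and `q(C)` keeping the full chain
dependency (one chain per chromosome).  Coordinate ascent on the evidence
lower bound (ELBO) repeats:

1. **Chain build** — emissions from the current `h`, `theta`; transition
   terms as the `q_k`-expectation of `log f` at breakend boundaries and the
   plain telomere penalty elsewhere.  Emissions are cached across sweeps in
   which `h` and `theta` did not change.
2. **Sum-product** — forward–backward in scaled-probability form (per-step
   max-shift; transitions applied as non-negative matrices), yielding
   single marginals, messages and the log-partition.  Pairwise marginals
   are materialised lazily from the messages only where needed.
3. **Breakpoint updates** — each `q_k` is refit exactly from the pairwise
   marginals at its two breakend boundaries; factors are independent given
   `q(C)`, so all are updated from the same marginals.
4. **Depth update** — an L-BFGS-B step (analytic gradient) maximising the
   marginal-weighted expected total-count log-likelihood over `h >= 0`,
   accepted only if the full expected log-likelihood (total + allele) does
   not decrease; otherwise the previous estimates are kept and flagged.
   Fitting the negative binomial dispersions is supported
   (`fit_dispersion`) but off by default: with 500 kb bins the dispersions
   are weakly identified within one sample and fixing them stabilises the
   mixture estimates.

Every step can only increase the ELBO; the value is tracked incrementally
(after the `q(C)` update it equals the chain log-partition plus the
breakpoint-factor entropies) and each restart's per-update trace is kept on
the result for auditing.  Convergence is a relative ELBO change below 1e−6
(at most 100 sweeps).

### Initialisation

Variational inference here is sensitive to initialisation, so restarts are
organised in two stages.  Stage 1 fits a *single*-tumour-clone model (12
states, cheap) over a grid of candidate normal fractions {0.2 … 0.8},
which pins the normal depth and the total tumour depth.  Stage 2 scans
descendant-clone splits {0.05 … 0.45} of that tumour depth; each candidate
runs its first three sweeps with `h` held fixed — committing the chain to
the candidate's mixture hypothesis before refining it — then one free
sweep, after which the two best candidates by ELBO run to convergence and
the overall best ELBO wins.  A flat (normal fraction × split) grid with
immediate depth updates reproducibly drifted out of the truthful basin;
with staged locking the final ELBO comparison reliably selects it.

### Outputs

Per-segment copy numbers are maximum-marginal states (ties resolved toward
lower total copy, then lower clone index, via the state ordering);
per-breakpoint copies are `argmax q_k`.  Mixture proportions are derived
from depths and inferred genome masses, `rho_m = h_m S_m / sum_j h_j S_j`
with `S_m = sum_n l_n c_nm` (normal mass fixed at `2 sum_n l_n`).  Tumour
clone labels are only identified up to permutation; evaluation scores under
the best label permutation.

## Baseline: breakpoint-naive HMM

The comparator clamps `b = 0` for every breakpoint, which collapses each
breakend transition to the plain telomere penalty — an ordinary
copy-number HMM sharing the exact code path (`b_max = 0`), so the collapse
is bit-identical by construction.  Breakpoint copies are then assigned post
hoc: per breakpoint, candidate per-clone copy vectors `0..b_max` are scored
exhaustively against the summed telomere count at its two boundaries and
the minimiser kept (ties toward smaller copies; breakpoints processed in
input order).  Because the allele-track choice couples clones, the
candidate vectors are scored jointly rather than per clone independently.

## Synthetic data generator

The simulator is first-class, tested code and defines the study conditions.
A two-clone phylogeny (normal → ancestral → descendant) accumulates
`n_events = 30` events — duplications and deletions (40% each) of
geometric extent (mean 20 segments, i.e. 10 Mb) on a random allele, and
balanced rearrangements (20%) — on a 10 × 50 Mb genome in 500 kb bins
(1000 segments).  Ancestral events are shared by both tumour clones;
descendant events are private, producing clonal divergence.  Unbalanced
events always emit both a breakpoint and a copy change (deletion breakends
oriented +/−, duplication −/+); balanced events emit breakpoints with no
copy change.  Events that would delete below zero copies or re-use a
boundary are re-drawn; breakends stay interior to chromosomes.

Histories are drawn by *scoring and re-sampling*: 100 candidate histories
are proposed and the one minimising the squared distance of realised
(tumour ploidy, divergent proportion) from the targets (defaults 2.3 and
0.3) is kept; replaying the stored event list reproduces the stored copy
numbers exactly.  Clones are labelled by lineage, not size, so ancestral/
descendant mixtures of x and 1−x are distinct conditions.

Read counts are then drawn from the same likelihood family used for
fitting (without the outlier component) at `depth = 0.02` reads per
nucleotide for a diploid mixture — about 10,000 pairs per 500 kb bin,
i.e. 30–40X WGS after containment filtering — with 25% of reads
allele-informative and beta-binomial allele noise.  False-positive
breakpoints can be injected at a configurable rate (default 0).  What this
generator does *not* emulate: GC/mappability bias in the counts (effective
length equals length in simulation), sub-bin event boundaries (events align
to the segment grid), more than two tumour clones, and read-level artefacts.
Passing recovery tests therefore demonstrate correctness of the inference
under the stated noise model, not robustness to real-data bias; the
aligned-read re-sampling pathway that would provide realistic bias requires
an external very-high-depth source dataset and is a documented stub.

## Evaluation

`score` reports length-weighted segment accuracy (both clones' folded
allele copies exact, best label permutation), exact-match breakpoint
accuracy under the same permutation, and relative plus absolute errors for
normal fraction, minor clone fraction, tumour ploidy and divergent
proportion.  `select_confident_subclonal` mirrors the standard filtering
for high-confidence subclonal breakpoints: drop segments < 100 kb, merge
adjacent segments with identical inter-clone allele copy difference, keep
merged segments ≥ 1 Mb with total copy ≤ 4, and keep subclonal breakpoints
whose both breakends adjoin a kept segment.  `classify_clonal_dynamics`
labels breakpoints ascending/descending/stable/conflicting by prevalence
change from one sample into two replicate later samples, with prevalence
`sum_{m: b_km>0} rho_m / sum_tumour rho_m` and missing breakpoints counted
as prevalence 0.  `assemble_chromosome` greedily walks clonally divergent
segments through subclonal breakpoints from a seed segment, deterministic
in table order, terminating at the first revisit (flagged as a cycle).

## Problem sizes and determinism

The shipped tests and the acceptance script run everything at desk scale:
enumeration oracles on chains of ≤ 6 segments and 9 states; monotonicity
on 60-segment genomes; recovery and model comparison on 1000-segment
genomes with 20 replicates per condition in the test suite and 8 per
condition in the acceptance script.  All randomness flows from explicit
seeds through `numpy.random.SeedSequence`; fits are deterministic given
their inputs and configuration.

## Known limitations

* Two tumour clones at most; the chain state space grows quadratically in
  per-clone states.
* The purity/ploidy ridge familiar from copy-number tools persists: for
  near-50/50 tumour mixtures, and when the descendant fraction is very
  small, solutions differing by clone rescaling approach equal ELBO.
* Breakpoint copy numbers for perfectly balanced rearrangements are not
  identifiable from segment counts (no copy change to absorb), and are
  typically inferred as zero.
* At most one breakend is modelled per segment boundary; later breakpoints
  mapping to an occupied boundary are ignored with a warning.
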