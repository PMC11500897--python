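# Methods

## Problem

Complex diseases are shaped by epistasis: joint effects of several SNPs on
disease risk that are invisible to single-marker association tests.  Given a
case-control genotype matrix (samples × SNPs, genotypes coded 0/1/2 as
minor-allele counts, phenotype 0 = control / 1 = case), the task is to find
the SNP *sets* (order ≥ 2) whose joint genotype distribution differs between
cases and controls — without enumerating all combinations, which is
infeasible beyond order 2 even at a few hundred SNPs.

`epissa` implements the Epi-SSA strategy: a sparrow-search swarm over
fixed-length SNP combinations, ranked by three complementary association
objectives, with a K2-guided backward elimination to purify candidate sets,
a G-test significance gate, and a post-hoc ratio filter against false
positives.

## Objectives and the contingency table

Every candidate is scored from the contingency table of its joint genotypes
x against the class y ∈ {0, 1}.  With m_x the count of samples in genotype
cell x and m_xy the per-class split:

* **K2** (negative log of the Cooper–Herskovits Bayesian score):
  Σ_x [ln((m_x+1)!) − ln(m_x0!) − ln(m_x1!)] for a binary phenotype.  The raw
  product underflows at realistic m, so the sum of log cell terms is used
  throughout; the minimization direction is unchanged.
* **CE**: the conditional entropy H(Y|X) = −Σ p(x,y) ln p(y|x), in nats.
  (Minimizing −H(Y|X) would reward *weak* association; the entropy itself is
  minimized, consistent with "lower = stronger" for all three objectives.)
* **Gini**: Σ_x p(x) Σ_y p(y|x)(1 − p(y|x)), the expected class impurity
  within cells.

All three are sums over occupied cells, so their values drift with the number
of occupied cells.  Two measures control that drift:

* **Auto order** mo = ⌊ln(min(m0, m1)) − 0.5⌋ caps the combination length so
  the average samples per cell stays near e (mo = 6 at 800+800).
* **Table cap** ml = ⌊min(m0, m1)/10⌋ (80 at 800+800): when a combination
  occupies more than ml cells, each objective keeps its ml − 1 smallest
  per-cell contributions and pools all remaining cells into one merged cell,
  scored as an ordinary cell.  Each objective orders cells by its own
  contribution.

The truncation makes *equal-length* position vectors comparable.  It is **not**
used in backward elimination, which compares sets of different sizes: there a
longer set would get to keep only its purest cells and could outscore a
genuinely associated subset.  Elimination therefore uses the untruncated K2,
whose per-cell penalty naturally favours the smallest set that explains the
phenotype.  (Measured on weak 2-SNP models, h² = 0.025: truncated-K2
elimination never descends below 5–6 SNPs; untruncated elimination recovers
exactly the planted pair.)

## Significance gate: the G-test

A purified set R of k SNPs is tested with the likelihood-ratio G-test,
statistic 2 Σ O ln(O/E) over observed cells, against χ² with
**df = (3^k − 1)(|Y| − 1)** — the full genotype space of the combination, not
just the observed cells.  This choice is deliberate and load-bearing: on
1600 samples a 6-SNP combination fragments the data into hundreds of small,
mostly pure cells, and with observed-cells df such tables reach p ≈ 10⁻¹⁰
under the null (the classic sparse-table inflation), burying true pairs.
With the full-space df the same tables land near p ≈ 1 while a true 2-SNP
interaction (df = 8) keeps its tiny p-value.  The generic table-level test
(`g_test_counts`) keeps the standard (r−1)(c−1) df, since a bare table has
no genotype space to refer to.  Findings pass at p ≤ cG (default 0.05, no
multiple-testing correction; the df convention plus the final filter carry
the false-positive control).

## The swarm

A population of n position vectors (mo distinct SNP indices each) is ordered
by **rankSum**: per-objective competition ranks (equal scores share a rank)
summed over K2, CE, Gini; ties break by raw K2, then insertion order, making
runs fully reproducible.  Each generation:

1. **Producers** — the best ⌊pd·n⌋ members (pd = 0.4).  One uniform draw per
   pass against the safety threshold st = 0.8 selects the regime: safe →
   each producer proposes a single-position mutation; unsafe → ⌊mo/2⌋
   positions are replaced.  Proposals are inserted, the population re-ranked,
   and the worse of {original, proposal} removed (ties keep the original).
2. **Scroungers** — the rest.  Members in the first half of the population
   cross over with the better of two randomly chosen producers (⌊mo/2⌋ own
   indices + the rest from the producer, distinctness enforced); members in
   the second half are redrawn entirely from the **pss** weight vector.
   Keep-the-better insertion as above.
3. **Scouts** — ⌊n·sd⌋ members chosen uniformly (sd = 0.2).  The incumbent
   best spawns a fresh pss draw; any other selected member crosses over with
   a strictly better producer (pss draw if none is better).  All spawned
   members are added, growing the population.
4. **Detection** — the top ⌊n·sd⌋ members are purified by greedy backward
   K2 elimination (remove the SNP whose deletion gives the lowest K2, while
   that K2 does not exceed the current set's; ties to the lowest index).
   Surviving sets of size ≥ 2 passing the G-test gate are stored,
   deduplicated on the SNP set with the first-seen record kept.  The pss
   weight of every SNP in each *examined* position vector decays by 0.9 —
   every generation, recorded or not.  This continuous decay is the
   exploration engine: SNPs the search keeps focusing on lose sampling
   weight, so pss draws sweep toward unexplored regions.  (With decay only
   on recorded findings, 1000-SNP runs leave pss essentially uniform and the
   planted pair is typically never visited.)  A 10⁻³⁰⁰ floor keeps weights
   positive.
5. **Trim** — spasChaos = (distinct SNPs in the population)/(population
   size × mo).  Below the threshold (0.6) the population has collapsed onto
   few SNPs (local optimum): the *best* ⌊n·sd⌋ members are removed to force
   escape; otherwise the worst are removed.  Size returns to n.

After maxG generations the stored findings are sorted by p (ties: smaller
set, then lexicographic names) and cut by the **iBiggest** rule: among the
consecutive ratios p_i/p_{i−1} (0/0 := 1, x/0 := ∞), the cut falls just
before the largest position attaining the maximum ratio; ties cut late
(retain more).  Zero p-values can never be cut, since the first nonzero p
produces the infinite ratio.  Lists of ≤ 2 findings pass whole.

## Simulator

Penetrance models assign each of the 3^k joint genotypes of k functional
SNPs a disease probability f(g); genotypes follow Hardy–Weinberg equilibrium
at each SNP's MAF, loci independent.  Derived: prevalence K = Σ P(g) f(g),
heritability h² = Σ P(g)(f(g) − K)²/(K(1 − K)), and per-SNP marginal
penetrances.  *No-marginal-effect* (DNME-style) models — every SNP's three
marginal penetrances equal — are found by alternating

1. an exact projection onto the equal-marginals affine subspace (one sweep
   of per-axis offsets suffices: each offset has zero P-weighted mean, so it
   preserves prevalence and every other SNP's marginals),
2. the affine rescale f ← K + c(f − K) with c = √(target h²/current h²),
   which preserves marginal equality and scales h² by c², and
3. clipping to [0, 1] (followed by re-projection when it bites),

from a random start, retried until both constraints hold within `tol`
(default 10⁻³).  Prevalence is left free, as in standard random-table model
generators.  Datasets are built by rejection sampling: functional genotypes
drawn from HWE, disease status Bernoulli(f(g)), until 800 cases and 800
controls (defaults) are filled; noise SNPs are independent HWE draws with
MAF ~ U(0.05, 0.5) — the lower bound avoids near-monomorphic columns.
Functional SNPs sit at uniformly chosen columns, named `M0P0…`, and are
recorded in a ground-truth manifest.

What the simulator does *not* emulate: linkage disequilibrium between loci,
population structure, genotyping error or missingness, and covariates.
Passing benchmarks therefore demonstrate the search and scoring machinery
under clean HWE sampling, not robustness to the correlation structure of
real GWAS panels.

## Evaluation

A finding is a true positive only under **exact set equality** with a
planted interaction — supersets count as false positives, since the
elimination step exists precisely to strip extras.  Per file:
recall = TP/(TP+FN), precision = TP/(TP+FP), F their harmonic mean (0 when
both are 0).  Per model: F is the *mean of per-file F values*, and Power is
the fraction of files in which every planted interaction was recovered.
Per-file seeds derive deterministically from (base seed, file index).

## Problem sizes

The packaged benchmarks run at reduced replicate counts chosen for a
single-CPU desk run: the 2-order grid (8 models: MAF ∈ {0.2, 0.4} ×
h² ∈ {0.025, 0.05, 0.1, 0.2}; 100 SNPs; 800+800; n = 20, maxG = 160) uses
20 files per model in the test suite (the full study design uses 100), and
the 1000-SNP benchmark runs as a 2-model × 10-file smoke at n = 40,
maxG = 3000 (the full design uses 8 models × 100 files at maxG = 6000–8000).
At 1000 SNPs the search has no marginal signal to follow and must *visit* a
pair before ranking can lock onto it, so power grows with the iteration
budget; the smoke's 3000 generations trade a modest power loss for a
several-fold shorter run, and the smoke uses the two h² = 0.2 models where
the per-visit detection probability is essentially 1.

## Numerical and design notes

* All factorials/Γ in log space; scores finite up to ≥ 10⁵ samples.
* Natural logarithms throughout (K2 and the G-test require them; CE's base
  only rescales ranks).
* Cell-selection ties in truncation resolve by cell index (stable order);
  competition-rank ties share a rank; removal ties in elimination go to the
  lowest SNP index; iBiggest ties cut late.
* One master RNG (PCG64, seeded by `SearchParams.seed`) drives every draw in
  a fixed call order; identical (dataset, seed) give byte-identical output.
  pss sampling without replacement uses sequential weighted draws with
  removal.
* "mo/2" in the update rules is the integer floor; the complementary share
  is mo − ⌊mo/2⌋, so odd-length vectors keep their length.
* In producer/scrounger updates the keep-the-better rule is applied
  uniformly in both regimes; equal rankSum keeps the incumbent.
* A hot-path numba kernel computes counts and all objectives per
  combination; a pure-numpy implementation of every objective remains the
  reference and the test suite cross-checks the two.  Rejected proposals
  restore the pre-insertion rank state exactly instead of re-ranking.
* Degenerate tables (a single observed genotype combination) inside the
  detection loop are treated as non-significant rather than raising, so the
  search continues; the public `g_test` raises on them.
* Models with marginal effects (DME-style) are supported through
  user-supplied penetrance tables (`read_penetrance_table`); the built-in
  searcher targets the no-marginal-effect family, which is fully
  parameterized by MAF and h².

## Known limitations

* The search is stochastic; on 1000-SNP panels with weak heritability a
  single run can miss the planted interaction (the full-scale protocol uses
  6000–8000 generations for this reason).
* The G-test df convention (full genotype space) is conservative for
  high-order sets with many unobserved genotype combinations.
* cG is applied without multiple-testing correction by default, matching the
  method's design; the conservative df and the iBiggest filter carry the
  false-positive control.  `SearchParams(bonferroni=True)` optionally divides
  cG by C(N, |R|) per purified set size.
* No handling of missing genotypes, covariates, LD or population structure.
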