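# Methods

`exoncnv` detects whole-exon deletions and duplications (exon CNVs) in
exon-targeted capture-panel sequencing from read depth alone.  Breakpoints of
germline exon CNVs usually lie in introns outside the captured targets, so
the only available signal is a coordinated drop (~0.5x) or rise (~1.5x) of
coverage across the affected exons, superimposed on large per-target probe
effects and per-sample library-size differences.  The package normalises
those nuisances away by comparing each test sample against an aggregate of
well-correlated samples from the same pool, models the resulting read
proportions with a beta-binomial, and segments copy number along the panel
with a three-state hidden Markov model.

## The count model

Let `t_i` be the test sample's read count at target `i` and `r_i` the summed
count of the chosen reference samples.  Conditional on the total
`n_i = t_i + r_i`, probe efficiency cancels exactly and

    t_i | n_i  ~  BetaBinomial(n_i, mu_c, phi)

where `mu_c` is the expected test proportion at copy number `c`.  At normal
copy (`c = 2`) the proportion is `mu`, fitted by maximum likelihood; other
copy numbers scale the odds by `c/2`:

    mu_c = c * mu / (c * mu + 2 * (1 - mu))        c in {1, 2, 3}

so a heterozygous deletion at `mu = 0.5` gives 1/3 and a duplication 0.6.
Overdispersion uses the intraclass-correlation parameterisation
`alpha = mu(1-phi)/phi`, `beta = (1-mu)(1-phi)/phi`; `phi = 0` is the
binomial.  A single global `phi` per test sample is fitted (the data carry
no information for a per-exon dispersion model at panel scale), bounded to
[1e-6, 0.5].  The lower bound is numerical: below it the likelihood is flat
to rounding error, and at panel depths it inflates the variance by under 1%.
Optimisation runs in (logit mu, log phi) with an analytic gradient
(L-BFGS-B); on failure the fit falls back to the pooled-proportion `mu` with
`phi = 1e-4` and a warning flag.

**Outlier-trimmed refit.**  The dispersion is meant to describe
*copy-neutral* targets, but the test sample may carry the very CNV being
sought.  On a small panel (49 targets here) a single genuinely altered exon
inflates the `phi` MLE several-fold, widening the model exactly where
discrimination is needed; measured on the synthetic spike-in study this
costs duplications ~20 points of sensitivity.  `fit_betabin` therefore
refits once after removing targets whose count is explained better by a
halved or 1.5x mean than by the fitted normal-copy model, with a
log-likelihood margin equal to the HMM's prior cost of opening a CNV
(`ln((1-2q)/q) ~ 4.6` nats at `q = 0.01`).  On copy-neutral data the trim
fires at the calling false-positive rate, i.e. it is a no-op.  On very large
panels the refit is immaterial either way.

## Reference selection

Candidates are ranked by Pearson correlation of raw per-target counts with
the test sample (targets with zero counts everywhere excluded; zero-variance
comparisons report correlation 0 with a warning).  For each prefix of the
ranking (k = 1..max_refs, default 10) the prefix's counts are summed into an
aggregate reference, the model is fitted, and the prefix is scored by the
*expected evidence for a heterozygous deletion*: the expectation, under the
CN1 emission distribution, of the CN1-vs-CN2 emission log-likelihood ratio,
summed over targets (a sum of KL divergences).  The prefix maximising this
criterion is chosen; ties go to the smaller set.

Two numerical/design notes:

* The expectation is evaluated by 32-node Gauss–Hermite quadrature with the
  exact (continuously extended) beta-binomial log-density as integrand.
  This matches full summation to ~4 significant figures at panel depths at
  <1 ms per prefix.  A closed-form normal-vs-normal approximation is *not*
  adequate here: its Gaussian tails over-penalise the mean shift and
  reverse the ranking's dependence on reference size.
* The chosen prefix is floored at `min_refs = 3` comparison samples when
  that many candidates exist.  With one or two references the criterion is
  evaluated on the same data that estimated `phi` and systematically
  rewards overconfident tiny references; empirically this shows up as weak
  spurious single-exon calls (grid-study specificity 98.5% -> 99.4% with the
  floor, sensitivity unchanged).  Both knobs are exposed as configuration.

Aggregation is by summation of the chosen samples' counts.  The selection
summary (best correlation, number of comparison samples) is attached to
every output row, because a negative report is only as good as the reference
that backed it.

## The HMM

States are copy numbers (1, 2, 3) per target, in panel order.  The initial
distribution is `(q, 1-2q, q)` — the first exon of each chromosome has the
same prior CNV probability as any other, so first-exon events are callable.
Transitions depend on the inter-target distance `d` (bp); with
`e = exp(-d/L)`:

    normal row:  (q, 1-2q, q)                       for all d
    CNV row:     stay e + (1-e)q;  to normal (1-e)(1-2q);  cross (1-e)q

This satisfies both limits that matter: at `d = 0` a CNV state persists with
probability 1, and as `d -> inf` (including chromosome changes, treated as
infinite gaps) every row collapses to the prior, making distant exons
independent.  Defaults `q = 0.01` and `L = 50 kb` (a typical germline CNV
scale) are exposed on the CLI since `q` directly trades sensitivity against
false discovery.  Decoding is exact Viterbi in log space; ties break toward
normal, then deletion (conservative for clinical review).  Maximal non-normal
runs become calls; runs never cross chromosomes.  Each call reports a log10
Bayes factor — the emission log-likelihood ratio of the called copy number
vs. normal summed over the span — plus observed reads, expected reads
(`sum round(n_i * mu)`), and their ratio.  Against a deep reference the
ratio sits near 0.5 / 1.5 for heterozygous deletions / duplications; with
few comparison samples the observed total drags the expectation and the
ratio compresses toward 1, which is why `n_comp` is reported alongside.

## Quality control

Two thresholds, both configurable and both *annotating* rather than
suppressing: a sample fails QC when its best candidate correlation is below
`min_correlation` (default 0.98 — the regime panel pools actually occupy;
below it the reference model is on thin ice), and a target fails when its
median raw count across samples is below `min_coverage` (default 100 reads).
Medians use the mean-of-central-pair convention; values equal to the
threshold pass.  Raw counts are used (the matrix is the native unit at this
stage).  A CNV carrier can legitimately fail sample QC — its own variant
depresses its correlation — which is a feature: the flag directs a human to
look.

## Simulation studies

**Spike-ins.**  Single-exon events are the hardest class, so sensitivity is
estimated by spiking: one cell (exon x random sample) of a CNV-negative pool
is scaled by 0.5 or 1.5 (rounded half-away-from-zero), that sample is
re-called, and a success is a call of the spiked kind overlapping the spiked
exon.  Defaults run 100 repeats per exon and kind (1,000 in the full-scale
configuration); per-(exon, kind) RNG substreams make exons independent and
results bit-reproducible.  A null spike (factor 1.0) measures the per-exon
false-call rate.

**Read resampling.**  Depth and pool-size effects are explored by binomial
resampling: each read contributes `Binomial(n, p)` copies with `n*p = f`,
the target depth ratio.  Operating at count level, the sum over a cell's
reads is a single `Binomial(n * count, p)` draw — distributionally identical
to per-read replication without needing alignments.  For `f <= 1` the choice
`(n=1, p=f)` is exact Bernoulli thinning, which maps Poisson coverage to
Poisson coverage; for `f > 1`, `n = ceil(10 f)` keeps the variance within
10% of the mean.  Each grid replicate draws a sub-pool without replacement,
resamples every cell, calls every member, and scores against the implant
truth; replicates whose pool contains no CNV carrier are excluded from the
sensitivity average, and all-carrier pools from the specificity average.
Sensitivity counts a truth variant as detected when a same-kind call in that
sample overlaps it by at least one target; specificity is the fraction of
CNV-negative samples with zero calls.

## Synthetic data generator

The generator emulates the statistical structure of exon-capture coverage —
what the caller's assumptions rest on — rather than any particular kit:

    count[i, j] ~ NegBin(mean = depth * e_i * s_j * c_ij / 2, size)

with probe efficiencies `e_i ~ LogNormal(0, 0.6)` shared across samples
(this sharing is what makes inter-sample correlation high, ~0.99, and
reference normalisation meaningful), library factors
`s_j ~ LogNormal(0, 0.1)`, negative-binomial size 500 (extra-Poisson CV
~4.5% per cell; `None` gives pure Poisson), and implanted copy numbers
`c_ij` in {1, 2, 3}.  The default panel is two BRCA-like genes — 23 exons
over ~80 kb (forward strand) and 26 exons over ~85 kb (reverse strand, so
custom exon numbers descend with coordinate) on separate synthetic
chromosomes — at ~1000 reads/target, the order of per-exon depth of a
48-plex capture pool on a rapid-run flow cell.  These are documented
assumptions, not measurements.  The dispersion/probe-spread defaults were
chosen so that default pools sit just inside the correlation regime the QC
thresholds presume (pairwise r ~ 0.99); noisier settings push pools below
the 0.98 QC bar, at which point negative reporting is not claimed anyway.

What the generator does **not** model: GC-dependent coverage, mappability,
batch effects, sample contamination, sex-chromosome ploidy, mosaicism, and
reference samples that are CNV carriers at the same locus (implants are one
per sample here; carrier-in-reference dilution does occur in the grid study
pools).  Passing the synthetic studies therefore demonstrates the machinery
is correct and well-calibrated under its own assumptions, not that real-data
performance will match: real panels add systematic coverage structure that
the correlation screen and QC flags must absorb.

## Known limitations

* **Panel-scale identifiability.**  With only two genes, an event spanning
  ~half of all targets (a whole-gene CNV here) is nearly indistinguishable
  from the complementary event in the rest of the panel plus a library-size
  shift; the fit absorbs it into `mu`/`phi`, and the caller can miss it or
  call its mirror image.  The QC correlation flag fires on such samples
  (0.88–0.98 observed).  On realistic panels (hundreds to thousands of
  targets) a whole-gene event is a small fraction of the panel and this
  degeneracy vanishes.  End-to-end tests accordingly use events up to about
  a quarter of the panel.
* Copy-number states are {1, 2, 3}: homozygous deletions are called as
  deletions (CN1 dominates CN2 by a wide margin) and amplifications beyond
  one extra copy as duplications; fractional/mosaic states are out of scope.
* Breakpoints are reported at target resolution; true breakpoints lie
  outside the captured exons.
* Counting is per read (not fragment), primary non-duplicate alignments
  with MAPQ >= 20 by default; no GC or mappability correction.

## Problem sizes used by the shipped studies

The test suite and the acceptance script run the spike-in study at 100
repeats per exon and kind (49 exons, two kinds: 9,800 re-calls) and one grid
cell (12-sample pools at 0.4x depth, 50 replicates: 600 re-calls), each on a
single CPU in a few minutes.  The full-scale configuration (1,000 repeats,
the complete pool-size x depth grid) is available through the same
functions and the CLI by raising `reps` and widening the grids.
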