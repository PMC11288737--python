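# Methods

`chiascan` analyses the quantitative signatures of a meiotic-sterility
phenotype in soybean (*Glycine max*, 2n = 40, twenty homologous pairs):
loss of interference-sensitive (Class I, MutLγ-dependent) crossovers. The
package has four analysis components and two generator components; this
note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Chiasma counts and the interference inference

A chiasma is the cytological footprint of a crossover. Counts are either
supplied directly per meiocyte or derived from bivalent morphology with
the standard convention: a ring bivalent (chiasmata in both arms) scores
2, a rod bivalent scores 1, a univalent pair scores 0. This convention is
consistent with a wild type averaging 38.5 chiasmata over 20 bivalents.

Crossover interference suppresses nearby crossovers, so Class I-dominated
counts are under-dispersed: the dispersion index (sample variance/mean,
n−1 denominator) is far below 1 (wild-type regime: 1.41²/38.50 ≈ 0.05).
Interference-insensitive (Class II) crossovers carry no such constraint;
a residuum of them is compatible with a Poisson distribution (dispersion
≈ 1). The test of that hypothesis is a one-sample Kolmogorov–Smirnov
statistic on the integer support,

    D = max_k | F_n(k) − F_λ(k) |,  k = 0 … max(counts),

with λ estimated by the sample mean unless supplied. For integer data the
supremum over the real line is attained at an integer no larger than the
sample maximum, so this evaluation is exact (verified in the tests against
a brute-force sup over every support point).

**p-values.** The classical KS limiting distribution assumes a continuous
null with no estimated parameters; on a discrete, parameter-estimated null
it is misspecified (conservative for discreteness, anticonservative for
estimation). The default is therefore a parametric bootstrap: B = 2000
Poisson(λ̂) resamples of size n, λ re-estimated on each, and
p = (1 + #{D\* ≥ D}) / (B + 1). The asymptotic mode (`method="asymptotic"`,
p from the Kolmogorov distribution at √n·D) is retained as a compatibility
switch. The rejection level defaults to α = 0.01, the level at which the
two study regimes separate. Calibration and power are checked by
simulation in the test suite: on true Poisson(8.41) data at n = 158 the
bootstrap rejects ≈ 1% of the time; on under-dispersed wild-type-like data
(mean 38.50, SD 1.41, n = 123) rejection is essentially certain. Degenerate
all-zero samples return p = 1 with a warning. Published P values from the
original cytology are not reproducible without the raw per-cell counts, so
all distributional claims here are properties of simulated data at the
printed summary statistics.

## Fertility under random univalent segregation

An achiasmate pair persists as two univalents that segregate independently
at anaphase I; each pair lands balanced (one univalent per pole) with
probability 1/2, so with u univalent pairs the balanced-set probability is
(1/2)^u. Two estimators are provided:

* **plugin** (default): u = n_pairs − mean bivalents, a fractional mean
  plugged into the exponent — e.g. u = 20 − 6.4 = 13.6 gives
  (1/2)^13.6 ≈ 0.008%.
* **distributional**: the exact expectation, the average of 2^−(n_pairs−b)
  over per-cell bivalent counts b. By Jensen's inequality it is ≥ the
  plugin value, with equality only for constant counts.

Reported percentages are rounded half-up to the printed precision
(so (1/2)^5 → 3.13%, (1/2)^10 → 0.10%), since banker's rounding would
print 3.12.

The Mendelian segregation test is the uncorrected two-class goodness-of-fit
chi-square against a stated ratio (3:1 by default), df = 1, with
consistency judged against the α = 0.05 critical value 3.84. The Yates
continuity correction is available behind a flag but off by default — the
uncorrected statistic is the one matching a two-class F2 count of 142:39
(χ² = 1.15; corrected ≈ 0.97).

Fold change of aberrant-mitosis frequencies is the plain treated/untreated
ratio to two decimals; 8.79/2.25 is reported as 3.91 even though a
published figure for that comparison reads 3.45 — neither the ratio nor
the relative increase (2.91) reproduces 3.45, so the arithmetic is
reported as computed.

## The meiosis simulator

Per homolog pair, crossover counts compose two pathways:

* **Class I**: optionally an obligate crossover (wild-type soybean shows
  20/20 bivalents in every cell, which only an obligate crossover
  reproduces as "20 ± 0.00"), plus an extra count with configurable mean
  and variance/mean (`class1_dispersion` ∈ (0, 1]).
* **Class II**: Poisson(`class2_rate`) per pair. With Class I disabled the
  per-cell total is exactly Poisson(n_pairs · rate).

Interference is modeled at the count level only; the evidence being
reproduced is count-distributional, so a spatial gamma-renewal placement
model would add parameters without adding testable structure.

**Under-dispersed draws.** The extra Class I count uses a three-point
distribution on {k−1, k, k+1} with k = round(mean), solved to match the
requested mean and variance exactly; when that system is infeasible (large
variances, or mean < 0.5) the fallback is a clipped normal with stochastic
rounding, which preserves the mean exactly (up to clipping) and meets the
variance to first order. With `class1_dispersion = 1` and no obligate
crossover the draw is exactly Poisson, making the two pathways
statistically indistinguishable — an equivalence the tests exploit.

Segregation: each achiasmate pair is balanced with probability 1/2,
independently — precisely the model behind the (1/2)^u algebra, so the
simulator doubles as its Monte-Carlo oracle. Lagging chromosomes are
Binomial(#univalents, `p_lag`), `p_lag` = 0.5 by default; only qualitative
agreement with observed anaphase spreads is claimed.

**Presets.** `wildtype`: obligate crossover, extra mean 0.925/pair,
dispersion 1.41²/38.50, Class II off → per-cell mean 38.50, SD ≈ 1.41.
`mlh1_mutant`: Class I off, Class II rate 8.41/20 = 0.4205 → per-cell
totals Poisson(8.41). The printed mutant means are mutually inconsistent
under a pure per-pair Poisson model: mean 8.41 chiasmata predicts
20(1 − e^−0.4205) ≈ 6.87 bivalents, not the observed 6.40. Whether
residual crossovers cluster on fewer pairs cannot be decided from summary
statistics, so the simulator leaves dispersion as a free parameter and the
preset reproduces the chiasma mean; the ≈ 0.47-bivalent offset is asserted
(as a property of the model) in the tests rather than hidden.

## BSA-seq scan

SNP index = ad_alt/(ad_ref + ad_alt) per variant, missing when total depth
< `min_depth` (default 8). Indices are averaged in 200-kb windows stepped
by 50 kb, anchored at position 0 of each chromosome (anchoring at the
first variant would make window boundaries depend on filtering); a window
is missing when fewer than `min_variants` (default 10) non-missing indices
fall in it. Windows with mean strictly > 0.9 merge into candidate regions
when overlapping or book-ended; regions are emitted as BED (0-based
half-open; VCF positions are 1-based). The depth and variant-count floors
are declared assumptions — the source protocol states neither — chosen to
stabilise indices at ~30× coverage. A Δ-index statistic (bulk − control
sample) is available; the default single-bulk index matches the >0.9
calling rule. InDels with AD fields are treated exactly like SNPs.

## Synthetic BSA bulk

The generator plants a recessive causal locus and simulates the selected
bulk plant by plant: every sterile F2 plant is homozygous at the locus, so
all 2·39 selected gametes carry the mutant allele there. Along the
chromosome each gamete's allele flips between adjacent markers with
probability r(δ) under Haldane's (no-interference) map function
r(d) = (1 − e^(−2d/100))/2, d in cM = bp/(kb_per_cM·1000). Because
1 − 2r composes multiplicatively, this Markov chain has exactly the
Haldane marginal r(d) at any distance from the locus while producing
spatially coherent haplotypes, as real gametes do. Read data are
Poisson(30) depths with binomial allele counts at the realised bulk
frequency. Defaults: a 40-Mb focal chromosome (typical soybean size),
markers every 2 kb (sparser than the ~2.9 variants/kb of a real bulk but
dense enough for ~100 markers per window), locus at 20 Mb, 400 kb/cM, and
a second 10-Mb chromosome unlinked to the locus (each gamete starts from a
fair coin) providing markers at r = 1/2 where the expected index is 0.5.
The true cM↔bp relation around the real locus is unknown; the scaling is a
stand-in configuration.

**What the generator does not emulate:** read-level errors, mapping
artefacts, duplicated or repetitive regions, uneven marker density, and
linkage disequilibrium structure beyond a single meiosis. Passing the
end-to-end test shows the scan logic recovers a planted locus under clean
binomial noise, not that it is robust to alignment pathology.

**A limitation found by simulation:** with a 39-plant bulk the realised
allele-frequency has SD ≈ √(p(1−p)/78) ≈ 0.03, which smears the >0.9
threshold crossing over megabases; the call therefore typically fragments
into 2–3 nearby regions rather than exactly one, under any admissible
noise model. The robust guarantees — asserted over 50 seeded replicates —
are that a candidate region *contains* the true locus and that the
highest-peak region is that one; single-region output should not be
expected at this bulk size.

## F2 phenotype generator

Sterile counts are Binomial(n, 1/4) under monogenic recessive inheritance
(n = 181 by default, the study's F2 size). The test suite checks the
chi-square consistency rate of these draws against the *exact* binomial
tail mass of the discrete statistic rather than a nominal 95%, since at
n = 181 the discreteness makes the true type-I rate differ from α.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; generator configs echo their seed (YAML) for provenance.
* Poisson tables truncate at λ + 10√λ by default with tail mass folded
  into the last bin, so expected-count tables sum exactly to n.
* Monte-Carlo test sizes (1000 calibration replicates, 300 power
  replicates, 10⁵-cell segregation oracles, 50 BSA replicates) were chosen
  so each check resolves its 3-SE band comfortably while the whole suite
  runs in a couple of minutes.
* Reported percentages round half-up at the printed precision; internal
  computation is double precision throughout.
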