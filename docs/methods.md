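# Methods

This note documents the models, normalizations and numerical choices behind
pombescreen, and what the synthetic-data generators do and do not emulate.

## Colony-array fitness screening

Colony sizes (pixel areas from plate-image quantification) are treated as a
multiplicative composition: strain growth x plate factor x positional factor
x measurement noise.  Plate-median normalization divides every size by the
plate's median of non-missing values, which removes plate-scale effects
exactly (the output median is 1 by construction) and makes fitness ratios
invariant to rescaling any single plate.  Replicate spots (up to four per
strain) are summarised by their median; the default pools spots across
plates before taking one median, with a per-plate-then-median strategy
available (`replicate_strategy`).  The fitness ratio is the treated median
over the untreated median, and the sensitive/resistant calls use strict
inequalities at 0.65 / 1.35 — a ratio exactly at a cutoff is neutral.

Missing colonies propagate as missing, never as zero: zero is a legitimate
measured size under a strong treatment, whereas a missing spot is a pinning
or imaging failure.  How missing spots on *control* plates enter medians is
a policy (`control_missing_policy`, default `drop`), since a dead control
colony is ambiguous between failure and genuine sickness.  Whether ratios
use plate-normalized or raw medians is likewise a flag
(`normalize_plates`, default on); normalizing first is the robust choice
when treated and control arms come from different pinning runs.

## SGA interaction scoring

The null model for a double mutant is multiplicative: expected fitness =
library single-mutant fitness x query fitness.  The control-query array
measures library single-mutant fitness directly, and the query-mutant
fitness is a plate-wide factor that plate-median normalization absorbs, so
no explicit query-fitness divisor is applied (one can be passed by scoring
against externally normalized medians).  After plate-median normalization,
row/column correction divides by row medians and then by the column medians
of the result (single pass, default) and re-centres the plate median to 1;
an iterative multiplicative median polish is available (`method="polish"`).
A separable gradient value = r(row) x c(col) is removed exactly by either.

The interaction score multiplies log10 of the query/control median ratio by
`score_scale` = 100.  The scale reconciles a log10 score with the +/-15
classification cutoffs, which then correspond to a 10^0.15 ~ 1.41-fold
deviation from expectation; it is a configuration constant, and the
classification counts are invariant to rescaling score and cutoff together.

Quality control computes three independent flag sets — linkage (within
30 kb, boundary inclusive, of the query locus or of the control-query
locus on its own array), small control colonies (raw median < 50 px,
strict), and high replicate variability (CV of quadruplicate normalized
sizes > `cv_max`, default 0.5, judged on each array separately; fewer than
two usable spots flags `insufficient_replicates`).  Because the sets are
computed independently, their union does not depend on application order.
Scores are still *reported* for flagged genes (so the artefactual negative
band around the query locus is visible in physical maps), but flagged genes
never carry a classification label or enter interaction counts.

## Chronological lifespan

Viability is per-replicate percent CFU relative to that replicate's day-0
count; day 0 is by definition 100%.  The log-rank statistic is built from
grouped counts: at each day the at-risk number is the previous day's CFU
(pooled over replicate series and rounded; a replicate-mean mode exists)
and events are the non-negative day-to-day decrements — CFU increases
(regrowth, plating noise) contribute zero events.  The statistic is the
standard (O - E)^2 / V chi-square with one degree of freedom.

Its p-value is computed by permuting replicate series between the two
conditions: exact enumeration of all label assignments when their number is
within the permutation budget (10,000 by default; 2x3 biological x technical
series per arm give C(12,6) = 924), otherwise seeded Monte Carlo.  The
reason is a property of the data-generating process, not a stylistic
preference: successive CFU counts are *independent plating samples* of a
declining culture, so day-to-day decrements carry Poisson-difference
variance, which is several-fold larger than the hypergeometric variance the
chi-square tail assumes.  Measured at the generator defaults, the
asymptotic tail rejects true nulls at ~18% instead of 5%, while the
permutation p is calibrated (~5%).  The asymptotic p is still reported as
`p_asymptotic`, since published CLS analyses conventionally quote it.
When series have different day grids the grids are intersected;
no interpolation is performed.

AUC is the trapezoidal area under the mean viability curve (%·days), with a
percentile bootstrap over replicate series (default 1000 resamples, always
seeded) for confidence intervals and condition differences.

## Micro-statistics

Septation index is a binomial proportion (percent, with sqrt(p(1-p)/n)
standard error).  Cell-length comparisons use the two-sided Mann-Whitney U
test — the groups are independent samples, so the rank-sum rather than the
signed-rank form — exact when the pooled sample is at most 12 and tie-free,
otherwise the tie-corrected normal approximation with continuity
correction.  qPCR fold changes follow the ddCt convention with an
alpha-tubulin (atb2) reference: per-replicate dCt subtracts the mean
reference Ct of the same run, so a constant plate offset cancels; fold =
2^(-ddCt); significance is a two-sided Welch t-test on the replicate dCt
sets (replicate wells of different runs are not paired units).

## Synthetic data: what it emulates, and what it does not

Generators compose colony sizes multiplicatively — base 400 px x plate
factor (lognormal, CV 0.10) x deterministic exponential row/column ramps
(amplitude 0.05 for screens; the same geometry for both arms of a plate
slot, as both are pinned and incubated identically) x strain effect x
lognormal spot noise (CV parameterized; 0.15 for screens, 0.10 for SGA).
Lognormal noise keeps sizes positive and matches the ratio scale on which
all effects are expressed.  Screen effects are 2-fold by default
(multiplier `effect_size` for resistant strains, its inverse for sensitive
ones); SGA double mutants multiply library single-mutant fitness (lognormal
across genes, CV 0.2), a query fitness of 0.9 and the injected interaction
multiplier; genes within the linkage window get multiplier 0.05, enough to
produce the characteristic negative band without modelling recombination.

CLS counts are Poisson draws around n0 exp(-(t/lambda)^k) with n0 = 500
colonies per plating, a day grid of 0..7 and Weibull shape k = 2 by default
(sigmoidal curves; k = 1 gives the exponential special case used for
closed-form checks).  The replicate structure is 2 biological x 3 technical
series per condition.  qPCR Ct values are Gaussian around gene-specific
baselines (~20-24 cycles; reference at 16) with 0.1-cycle noise.

Not emulated: pinning-robot artefacts beyond a uniform missingness rate,
agar defects, batch effects between media lots, colony-size saturation at
high density, and any sequencing readout.  Passing recovery tests therefore
demonstrate that the pipeline inverts its own generative assumptions at
realistic noise levels — not that those assumptions exhaust real plate
pathology; the quality-control flags exist precisely for the residue.

## Problem sizes and determinism

Recovery suites run at 1000 strains (screens), 1500-2000 genes (SGA), 500
simulations (log-rank calibration) and 100 seeds (qPCR) — sizes at which
the Monte-Carlo error of each measured rate is small against its acceptance
margin while a full run stays interactive.  Every stochastic routine takes
an explicit seed; generators draw from a single numpy Generator so that one
seed reproduces an entire experiment bit-for-bit.

## Known limitations

- The grouped log-rank treats pooled replicate counts as one risk set;
  biological and technical replicates are exchangeable under permutation
  but their variance components are not modelled separately.
- Fitness calls are hard-thresholded; no error model or multiple-testing
  control is attached to the sensitive/resistant lists (the screens are
  hypothesis-generating, and downstream enrichment is out of scope).
- The SGA score has no per-gene significance; the +/-15 cutoff plays that
  role, as in the source workflow.
- Physical maps use a single representative coordinate per gene; linkage
  exclusion is symmetric and ignores centromere/telomere recombination
  structure.
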