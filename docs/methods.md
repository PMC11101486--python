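# Methods

## Scoring model

Immunoreactivity is quantified on the two-level intensity convention:
each cell is graded 0 (no chromogen), 1 (faint/fine deposition) or 2
(prominent deposition), and the H-score is the intensity-weighted sum of
cell percentages, `H = p₁ + 2·p₂ ∈ [0, 200]`.  Staining-profile
percentages must sum to 100 within ±0.5 — the tolerance absorbs
pathologist rounding.  Positivity is the inclusive cut `H ≥ 20`
everywhere; every threshold comparison in the package uses `≥`.

Molecular subtype is the cross of two binary axes.  An axis is positive
when **any** scored marker on it (AR-axis: AR, NKX3.1; NE-axis: SYP,
INSM1) reaches its threshold; the subtyping framework this emulates is
defined in prior literature without a restated rule, so the disjunction
— consistent with the package-wide ≥20 convention — is a documented
assumption, and `SubtypeRule` supports per-marker thresholds and an
all-markers conjunction for fidelity to other conventions.  A sample
with no scored marker on either axis is unclassifiable, never silently
assigned.

Lesion-level (per patient-site) H-scores aggregate samples by maximum by
default: a site "expresses" a target if any of its samples does, the
conservative choice for target presence; mean aggregation is available.
Expressor categories partition each patient-marker with ≥1 scored site:
uniformly negative (all sites < 20), heterogeneous (sites on both sides),
uniformly positive (all ≥ 20).

## Reporting conventions

Co-expression percentages are rounded half-away-from-zero to integers,
except values in [3.5%, 5%), which keep one decimal so that small
fractions just below the 5% reporting threshold are not overstated
(e.g. 3/71 → 4.2, while 7/304 → 2 and 61/304 → 20).  Both band edges are
arguments of `format_percentage`.  Rounded four-cell percentage sets sum
to 100 within ±0.5 per cell.  Denominators are always the evaluable set:
lesions missing a call for either marker of a pair are excluded from
that pair's total, and patients with no scored site are excluded from
expressor distributions, so different analyses may legitimately report
different denominators for the same cohort.

## Heterogeneity index

The estimand is the probability that a random within-unit pair of
binarized calls disagrees.  Grouping units: tumor blocks with ≥2 scored
samples (intra-tumoral) and patients whose scored samples span ≥2 blocks
(inter-tumoral, counting only cross-block pairs).  For a unit with `p`
positive and `n` negative samples and all pairs eligible, the discordant
fraction is `p·n / C(p+n, 2)`; for cross-block restriction, within-block
pairs are subtracted from both numerator and denominator.

The point estimate follows a two-stage sampler, 1000 pairs by default:
draw a unit uniformly at random, then an eligible pair uniformly within
it, with replacement across draws.  Uniform unit weighting avoids
overweighting heavily sampled patients; pooled weighting (units by their
eligible-pair count, equivalent to drawing pairs uniformly from the
pooled pair population) is available via `weighting="pooled"`.  The
discordance indicator of a uniform pair from unit *u* is exactly
Bernoulli(*dᵤ*), which is how the sampler draws outcomes — pair
identities are never needed.  `exhaustive_discordance` computes the
exact expectation by enumeration and serves as the oracle in tests.

Confidence limits are BCa bootstrap intervals.  The resampling unit is
the grouping unit — never the individual pair — so clustering is
respected; each replicate recomputes the *exhaustive* statistic on the
resampled units, and the acceleration constant comes from
leave-one-unit-out jackknife values.  Recomputing the Monte-Carlo pair
sampler inside each replicate instead would inject sampler noise into
the bias-correction term z₀ and measurably degrades calibration
(empirical 95% coverage ~0.88 versus ~0.93 with the exhaustive replicate
statistic in the packaged calibration simulation); the bootstrap is
meant to quantify cohort-level sampling uncertainty, not the reducible
noise of the pair sampler.  z₀ is the normal quantile of the fraction of
replicates below the exhaustive point value (ties counted half, clipped
away from 0 and 1 by 1/(B+1)); endpoints are adjusted percentiles
clipped to [0, 1].  A degenerate replicate distribution (all equal —
e.g. fully concordant data) collapses the interval to the point with a
flag.  The reported estimate remains the pair-sampled one; if its
Monte-Carlo noise would place it outside the interval, the interval is
widened to contain it, preserving `ci_low ≤ estimate ≤ ci_high`.

## Association models

**Site means.** H-scores regress on anatomic-site fixed effects with a
patient random intercept (REML); differences are reported against a
reference site (vertebral bone by default) with Wald 95% limits.  When
no patient contributes more than one sample, or the patient variance
component is estimated at (or within 1e-4·residual of) the zero
boundary, the fit is replaced by ordinary least squares — at that ratio
GLS and OLS are numerically indistinguishable, and the replacement makes
the reduction exact rather than optimizer-dependent.  Sites observed in
a single sample are kept but flagged `wide_ci`.

**Expression–genotype.** Binary positivity (patient-level "any lesion
positive" by default, since genomics is per patient; per-lesion mode
available) regresses on alteration status.  With one observation per
patient this is ordinary logistic regression, whose odds ratio equals
the 2×2 cross-product ratio; with repeated observations a binomial GEE
with exchangeable working correlation and robust (cluster) standard
errors is used.  The contract is estimation behavior — reduction to the
ordinary model and parameter recovery — not a specific estimator.

Separation is detected from the 2×2 table before fitting.  Complete
separation (alteration status perfectly predicts the outcome: both
off-diagonal or both diagonal cells empty) yields a flagged result with
no finite odds ratio.  A single empty cell puts the MLE at the boundary:
the sample odds ratio (0 or ∞) is reported with the exact conditional
interval (Fisher's noncentral hypergeometric) and a Fisher exact
p-value, flagged `quasi_separation` + `boundary_estimate`.

RB1 is analyzed twice by default — biallelic inactivation only, and any
alteration — because the two contrasts answer different biological
questions; under `biallelic_only`, monoallelic carriers count as
unaltered.  p < 0.05 is the declared significance level and no
multiple-testing correction is applied by default (a Benjamini–Hochberg
helper is deliberately out of the default path).

Continuous expression (FPKM-like) is dichotomized by median split by
default, positive strictly above the cut (ties negative); a fixed cutoff
rule is inclusive (`≥`), matching the H-score convention, so
`fixed_cutoff(20)` on H-scores reproduces `binarize_expression` exactly.
The median rule is a documented default, not a claim about any external
dataset's rule.

## Synthetic cohort generator

The generator emulates the structure of a multi-site rapid-autopsy
cohort at its published scale: 52 patients; sites per patient
zero-truncated Poisson (mean 7, capped at the 11-label site vocabulary,
targeting ~372 sites); samples per site 1 + Poisson(1) (~753 samples);
subtype mixture 0.62 / 0.19 / 0.07 / 0.12 over AR+/NE−, AR−/NE+,
AR+/NE+, AR−/NE−, approximating the published lesion composition (304
of ~372 evaluable AR+/NE−, 71 AR−/NE+).  Each site keeps its patient's
dominant subtype with probability 0.9 (`dominant_subtype_fidelity`),
creating the mixed-phenotype patients in which heterogeneous expression
concentrates.

Marker H-scores are zero-inflated scaled Beta per (marker, subtype):
mass π₀ at zero plus `200·Beta(a, b)`, capturing the bimodal
negative-versus-expressing pattern of IHC dot plots.  Defaults are tuned
to published per-subtype medians (TROP2 ~200 in AR+/NE−, ~0 in AR−/NE+;
DLL3 ~90 in AR−/NE+; CEACAM5 ~60 in AR−/NE+; PSMA high in AR-driven
disease) without claiming the true distributions, which are published
only as medians and ranges.  Scores are emitted as staining profiles
(a random valid p₀/p₁/p₂ decomposition of each H-score), so downstream
analyses must run the scoring path.  Gene alteration statuses are drawn
per patient conditional on dominant subtype; RB1 biallelic loss is
enriched in AR−/NE+ and AR alterations in AR-driven subtypes.

Every estimand is available in closed form. Within-unit pair
discordance: intra-tumoral `Σ_s P(S=s)·2pₛ(1−pₛ)` over the site-subtype
marginal; inter-tumoral `Σ_d π_d·2q_d(1−q_d)` with `q_d` the
site-marginal positivity given dominance (cross-block pairs have
independent site subtypes given the dominant one, so both expressions
are exact expectations of the unit-then-pair sampler).  Patient-level
positivity marginalizes the sample- and site-count distributions
analytically (shifted-Poisson generating function; exact finite sum over
the capped site-count pmf), giving exact log odds ratios between
alteration and any-site positivity.

What the generator does **not** emulate: spatial within-slide structure,
scorer disagreement, correlated sample selection (samples within a site
are iid given the site subtype — real serial sections are more
correlated, so generated intra-tumoral heterogeneity runs higher than
published values), missingness mechanisms, and any direct causal effect
of genotype on expression beyond what subtype mixing induces.  Passing
recovery tests therefore demonstrates estimator correctness under the
stated hierarchical model, not fidelity of any particular real cohort.

## Numerical and design choices

* Problem sizes in the packaged simulations (200 replicates for
  calibration checks; 25–50 patients for coverage cohorts; 1e5 pairs for
  oracle-equivalence checks) are chosen so each check resolves its
  target tolerance with comfortable Monte-Carlo margin.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical (inputs, config, seed)
  reproduce every output bit.  Functions with stochastic behavior refuse
  to run without a seed.
* The canonical cohort format is long/tidy CSV (one row per
  sample-marker); wide H-score tables are melted through a column map on
  read.  Missingness is per (sample, marker), never per whole sample.
* Unknown anatomic-site labels map to `other` with a warning rather than
  an error; unknown marker names and genomics status tokens are errors.
* Fixtures encoding published summary counts are synthetic stand-ins
  constructed from the printed site-level contingency and per-patient
  category counts; the underlying per-sample tables are not published.

## Known limitations

* The inter-tumoral level treats any two distinct blocks symmetrically;
  anatomical distance between sites is not modeled.
* GEE provides population-averaged odds ratios; a subject-specific
  random-intercept logistic would give larger absolute log odds under
  strong clustering.  With patient-level positivity (the default) the
  distinction vanishes.
* BCa intervals inherit bootstrap small-sample behavior: with very few
  grouping units (< ~10) coverage is not guaranteed and the degenerate
  flag becomes common.
* The heterogeneity index conditions on units with at least one eligible
  pair; cohorts dominated by single-sample sites carry little
  information at the intra-tumoral level and none at the inter-tumoral
  level for single-block patients.
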