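# Methods

`studbook` analyses closed-registry pedigrees: per-animal inbreeding and
pairwise kinship, cohort-level trends in inbreeding, effective population
size, generation intervals and the concentration of sire usage. This note
records the models, conventions, numerical choices and known limitations.

## Pedigree model and conventions

A pedigree is one record per registered animal: identifier, sire, dam, sex,
birth date and breed. Missing parents are encoded in files as an empty
field, `0` or `NA`. A *founder* has both parents unknown; founders are
assumed non-inbred and mutually unrelated. An animal with exactly one known
parent is not a founder — the unknown side simply contributes no
co-ancestry, so such animals have F = 0 themselves but transmit kinship
through the known side. Registries do not document how half-known parentage
should be treated; this is the conventional choice and is flagged here as an
assumption.

Parents referenced but not listed are materialised as founder stubs (sex
inferred from the role they appeared in). Identifiers match by exact string
comparison after whitespace trimming, without case folding, because registry
names can be case-significant.

Dates are ISO dates or bare 4-digit years. If any record carries a
year-only date, the whole pedigree is treated as year-resolution: ages
become integer year differences (offspring year − parent year). At date
resolution ages are day differences divided by 365.25. Records with no date
at all are permitted and simply excluded from age-based statistics.

Chronology violations (offspring born on or before a parent's birth, or a
parental age above a configurable maximum, default 20 years) are *soft*
issues: real registries contain them. Affected records are excluded from
age-based statistics only, never from relatedness computation. Hard errors —
duplicate identifiers, self-parentage, ancestry cycles, unparseable dates —
abort the read.

## Inbreeding and kinship

The coefficient of inbreeding F is the probability that an animal's two
alleles at a locus are identical by descent; it equals the coefficient of
kinship f of its parents. F for all animals is computed with the
Meuwissen–Luo tabular algorithm: writing the numerator relationship matrix
as A = T D T′ (T the gene-flow path matrix, D the diagonal of within-family
segregation variances), the self-relationship is

    A_ii = 1 + F_i = Σ_j L_ij² D_j

summed over the ancestors j of i, where the L coefficients are accumulated
by a youngest-to-oldest sweep of the ancestor set (L_parent += L_child / 2)
and D_j = ½ − ¼(F_sire(j) + F_dam(j)), with an unknown parent entering as
F = −1 so that founders get D = 1. The cost per animal is bounded by its
ancestor count, so 10⁵–10⁶-record registries are tractable; the inner loop
is JIT-compiled (a pure-Python twin of the kernel is the reference
implementation and the fallback).

Pairwise kinship uses the same decomposition restricted to the union of the
two ancestor sets: a_xy = Σ_j T_xj T_yj D_j and f = a_xy / 2. No full
relationship matrix is ever materialised; for a sample of animals the T rows
are assembled over the ancestor union and the kinship block follows as one
matrix product. Self-kinship is f(x,x) = (1 + F_x)/2. All quantities are
dyadic rationals computed in double precision without intermediate rounding;
reports print 6 decimals.

## Cohort series: observed and expected inbreeding

For each birth year the *observed* inbreeding is the mean F of the cohort.
The *expected* inbreeding is the cohort's mean pairwise kinship — the F its
offspring would have under random mating. Because all ½(n²−n) pairs are
expensive for large cohorts, the estimate follows a size-dependent regime:
all pairs when n ≤ 500; all pairs within one uniform random sample of 500
(without replacement) when 500 < n ≤ 2000; and ten independent samples of 50
when n > 2000, reporting the mean and the sample standard deviation of the
ten sample means. Self-pairs are never included (they are not matings), and
sampling pools both sexes — the restriction to feasible (opposite-sex) pairs
is not applied; both choices are assumptions documented here. A run-level
seed deterministically derives one substream per year, so extending the year
range never perturbs other years' samples.

The expected series is plotted/reported *staggered* forward by the
generation interval: animals born in year t breed around t + L, so their
mean kinship predicts observed inbreeding about L years later. The offset is
round-half-up of L to whole years (the underlying quantity is annual);
values shifted past the data window are retained and flagged.

## Rates, effective population size, blocks

The rate of inbreeding per annum is the negated OLS regression coefficient
of ln(1 − F_t) on year of birth over cohort years with at least one birth,
unweighted (a cohort-size-weighted variant exists but is off by default,
since the reference procedure does not weight). Negation makes the rate
positive when inbreeding rises. The literal regression-coefficient rate is
the default; `transform="exp"` returns 1 − exp(b), the exact per-annum rate
implied by a log-linear decline of 1 − F — the two differ only at third
order at realistic rates (fidelity first, exactness available).

The per-generation rate is ΔF = rate × L, and the effective population size
is Ne = 1/(2ΔF): the size of an idealised population with the same
per-generation inbreeding increment. ΔF ≤ 0 (diversity stable or rising)
yields an `Undetermined` Ne carrying a machine-readable reason code
(`negative_rate` / `zero_rate`) rather than an exception, so batch reports
never abort; ΔF = 0 is distinguished from ΔF < 0 by its code.

The generation interval L is the mean age of parents at the birth of progeny
that themselves reproduce, pooled per offspring birth year, with L the
unweighted mean of yearly means. "Reproduces" means having at least one
offspring anywhere in the pedigree, without bounding the lookahead window.

Block statistics partition the window into 5-year blocks (seven blocks for
1980–2014). Within-block trends re-estimate the regression slope only; the
whole-period L is reused because a 5-year window estimates L poorly and the
per-block generation interval is descriptive. Blocks with fewer than 3
usable years are `Undetermined(insufficient_years)`. A breed enters
cross-breed block comparisons only with a mean of more than 50 registrations
per year in every block; across-breed block differences are tested by
one-way ANOVA with breeds as replicates within blocks.

Sire-usage concentration per year and role: progeny counts per unique
parent; max/mean/median/mode/sd (sd with n−1 denominator, reported as 0 and
flagged when only one parent; the smallest modal value is reported and
multimodality flagged); and pct_top[q], the share of known-parent
registrations born to the most prolific ⌈q% of parents⌉, with the top set
chosen by descending count and ties broken by ascending identifier
(deterministic; ceiling guarantees a non-empty set). Registrations with an
unknown parent of the role are excluded from the denominator — the
alternative (counting them) is a documented open convention.

## The synthetic registry generator

No public registry accompanies the analysis, so the generator emulates a
closed studbook with known ground truth: year cohorts, a per-year number of
breeding sires and dams drawn from age-eligible earlier cohorts, Poisson (or
fixed) litters per dam, offspring sex by fair coin, and full birth dates
within the year.

*Popular sires.* Every male carries a persistent popularity score drawn at
birth. Stud slots are filled in descending popularity over the eligible
cohorts, so a sought-after male keeps his place for his whole career, and an
offspring's sire is drawn with weight ∝ (1 − s)^rank over the year's stud
list. `sire_skew` s = 0 gives uniform usage; s → 1 gives a single dominant
sire whose grand-progeny all have F = 0.125 (the textbook popular-sire
scenario, reproduced exactly by the `popular-sire-extreme` preset). Because
the score is independent of the pedigree, a skew-0 draw is still a uniform
random subset of each cohort. A per-year random re-ranking was considered
and rejected: under overlapping generations it dilutes the concentration
roughly by the generation length in years and does not model the persistence
of real popular sires.

*Migration.* With per-year probability `migration_rate`, a breeding slot is
filled by a novel unrelated founder. Migrants carry no hidden co-ancestry,
so the underestimation of ΔF caused by truncated migrant pedigrees in real
registries is absent here by construction (it can be studied by truncating
ancestry on output while keeping the full truth).

*Ground truth.* With no skew and no migration the system is Wright's
idealised two-sex population: expected ΔF = 1/(8Ns) + 1/(8Nd) per
generation and Ne = 4NsNd/(Ns+Nd) (harmonic means over breeding years when
the census varies). The default parental age is a point mass at 4 years —
non-overlapping generations, so these closed forms apply cleanly; the
verification suite checks recovery of the Ne grid {10,25,50}² within 25%
from 15-generation simulations averaged over 20 replicates, averaging
the per-generation rate across replicates before inversion (inverting
per-replicate and averaging Ne would be biased upward by Jensen's
inequality).

*Scenario presets.* The library encodes three qualitative breed histories
(plus the exact popular-sire example): `contraction-then-recovery` (strong
sire concentration and a small dam census easing over 1976–1994, migrant
stock accelerating after 2000), and the census-contrast pair
`vulnerable-native` / `common-large` (identical skew and migration
histories; only the census scale differs). Three design findings shaped the
presets, all visible in their configurations: (i) a point-mass parental age
splits the population into isolated year-lineages whose mean-F sawtooth
corrupts 5-point block regressions, so presets use an overlapping age
distribution {3: 0.25, 4: 0.5, 5: 0.25} (L = 4); (ii) founder-cohort echo
waves take several generations to damp, so presets begin in 1946 although
analysis windows start in 1980; (iii) the per-generation rate is convex in
the skew parameter, so driver ramps are specified linearly in
effective-number reciprocals (a = s/(2 − s) for the sire side, 1/Nd for the
dam side), which makes the expected block-level decline steady. The
contraction preset's mean block ΔF declines strictly across all seven
blocks with post-2000 blocks negative; the vulnerable-native preset shows a
larger early-block ΔF than the common preset. These are stochastic
signatures verified on replicate averages (80 and 30/15 replicates in the
suite).

*What the generator does not emulate*: litter structure beyond a per-dam
Poisson/fixed count, seasonal breeding, selection on traits, registry
transfer records, hidden migrant co-ancestry, and sub-population structure.
Passing tests therefore demonstrate correctness of the estimators under the
stated breeding model, not robustness to every pathology of real registry
data (incomplete early pedigrees being the most consequential omission).

## Problem sizes and determinism

The verification suite uses pedigrees of 10³–4×10⁴ animals per simulation
(up to ~30 s of aggregate simulation per property) and Monte Carlo gene
dropping at 2×10⁵ drops as an identity-by-descent oracle; these sizes were
chosen so the stochastic checks are statistically decisive while the full
suite stays in the minutes range. All
randomness flows from explicit integer seeds: identical configuration and
seed give byte-identical pedigrees and reports (report regeneration is
byte-stable except the timestamped run log).

## Known limitations

* One-sided parentage and founder assumptions understate co-ancestry when
  parentage is missing non-randomly.
* The annual-rate regression assumes ln(1 − F_t) is approximately linear
  within the window; strong within-window regime changes belong in block
  analyses, not the whole-period estimate.
* Ne from 5-point block regressions is noisy for small breeds; treat block
  Ne as descriptive, not inferential.
* The ANOVA across breeds treats breeds as independent replicates, ignoring
  shared ancestry between breeds and unequal breed sizes.
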