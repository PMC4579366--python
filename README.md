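# studbook

Pedigree-based population analysis for closed studbook registries (dog
breeds, rare livestock, zoo populations): exact inbreeding and kinship
coefficients, rates of inbreeding, effective population size, generation
intervals and popular-sire usage statistics — plus a synthetic registry
generator with known ground truth for validating the whole pipeline.

## The problem

In a closed registry every animal's ancestry traces back to a finite founder
set, so inbreeding is inevitable; what matters for the health of a
population is how *fast* mean inbreeding rises. `studbook` computes, per
breed:

* **F**, the coefficient of inbreeding of every animal — the probability
  that its two alleles at a locus are identical by descent — via the
  Meuwissen–Luo tabular algorithm (cost per animal bounded by its ancestor
  count; whole-registry scale);
* **f**, pairwise kinship (f of two animals equals the F of their
  prospective offspring), evaluated tabularly over ancestor-set unions;
* cohort series of observed inbreeding (mean F by birth year) and expected
  inbreeding (mean cohort kinship under random mating, sampled for large
  cohorts, staggered forward by the generation interval);
* the **rate of inbreeding**: per annum as −b where b is the OLS slope of
  ln(1 − F̄ₜ) on birth year; per generation as ΔF = −b·L with L the
  generation interval; and the **effective population size**
  Nₑ = 1/(2ΔF), undetermined (not an error) when ΔF ≤ 0;
* generation intervals, registration trends, progeny-per-sire
  concentration (max/mean/median/mode/sd and the share of registrations
  from the top 50/25/10/5 % of sires), 5-year-block summaries and
  across-breed block ANOVA.

## Worked example

Simulate a small registry with moderately concentrated sire usage and run
the full per-breed report:

```python
from studbook import SimConfig, simulate, run_report

cfg = SimConfig(years=(1975, 2014), n_sires=10, n_dams=15, litter_mean=4.0,
                sire_skew=0.4, seed=21, breed="Demo")
ped, truth = simulate(cfg)
rep = run_report(ped, "demo_report", window=(1980, 2014), seed=0,
                 compute_expected=False)
t = rep.whole_trend
print(f"records: {len(ped)}")
print(f"L = {rep.L:.2f} years")
print(f"dF_annual = {t.dF_annual:.6f}  dF_gen = {t.dF_gen:.6f}")
print(f"Ne = {t.Ne:.1f}")
```

prints

```
records: 2263
L = 4.00 years
dF_annual = 0.008583  dF_gen = 0.034316
Ne = 14.6
```

Read: parents average 4.0 years of age when their (breeding) offspring are
born; mean inbreeding rises at 0.86 % per year, i.e. ΔF ≈ 3.4 % per
generation — far above the 1 % sustainability guideline — equivalent to an
idealised population of ≈ 15 animals. The skew matters: with uniform sire
usage the same census would give Nₑ = 4·10·15/25 = 24. The report
directory contains `registrations.tsv`, `usage_sire.tsv`/`usage_dam.tsv`,
`cohort_series.tsv`, `trend_blocks.tsv` (whole period + seven 5-year
blocks) and a machine-readable `summary.json`.

A command-line interface wraps the same pipeline:

```bash
studbook simulate --preset contraction-then-recovery -o breed.csv --seed 1
studbook report breed.csv -o report/ --window 1980 2014
studbook validate breed.csv
```

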