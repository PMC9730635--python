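# Methods

## Data model

The observation unit is a plant-month: head counts slaughtered per species
category (turkey, griller chicken, heavy chicken) and condemnation counts
per cause, with partial and total dispositions pooled — the source
spreadsheets this model mirrors do not separate them, so no statistic in
the package attempts to. A month can be *absent* (simply not in the
series) or *excluded* (present but flagged inconsistent); excluded months
are carried in the data but contribute to no index, ratio, correlation or
test. Frequency accounting is the one exception: it is a descriptive
total of everything recorded and includes excluded months by default.

Condemnation counts may in principle exceed head counts (one carcass can
generate several partial-condemnation records), so ingestion warns rather
than rejects when that happens.

The cause registry is configuration: the default ships the twelve causes
of the motivating data, with contamination, contusion/traumatic injury and
excessive scalding flagged *technological* (process failures) and the
seven pathogen/hygiene/climate-associated causes (dermatosis,
aerosacculitis, arthritis, septicemia, disgusting aspects, cellulitis,
ascitic syndrome) flagged eligible for seasonal analysis. Cachexia and the
catch-all bucket are kept out of seasonal analysis because of their low
and heterogeneous occurrence.

## Indices

**COI** is `scale · condemned/slaughtered` with `scale = 10⁶` by default
(condemnations per million head; any positive scale is accepted and the
index is exactly scale-equivariant). Period versions pool numerator and
denominator over the period — they are not means of monthly indices.

**ASI** is the two-stage ratio-to-annual-mean construction. Design points
worth recording:

* The annual mean in stage one uses only that year's usable months, so a
  partial final year (e.g. January–November) and years with excluded
  months are handled by the same rule. A consequence: every complete
  year's ratios average to exactly 1, which the tests assert as an
  algebraic identity.
* Stage two is an unweighted mean across years, not weighted by slaughter
  volume — the construction treats years as exchangeable replicates of a
  seasonal profile.
* When a calendar month has no usable year anywhere in the series it is
  absent from the result (with a warning), not zero.
* Where a historical description of this construction enumerates one
  December fewer than the calendar contains, the package resolves the
  ambiguity by averaging *all* usable Decembers; the per-month year counts
  are always reported so the divisor is visible.
* The index is invariant to rescaling the whole series or any single
  year's months by a positive constant; both invariances are property
  tested.

**Frequency table.** The percent denominator defaults to the sum of the
cause counts themselves, which is the only internally consistent choice
when an externally reported grand total disagrees with the column sum (as
the motivating published table does, by about 4.6%). The
`reported_total` policy is available and logs the discrepancy when the two
differ.

## Inference

* **Group comparison** (turkey-era months A vs heavy-chicken-only months
  B, on per-month ratios of 100·condemned/slaughtered): Welch's
  unequal-variance t test. The groups are strongly unbalanced (110 vs 21
  months under the reference schedule) with very different spreads, so the
  pooled-variance test's assumptions would be untenable. The headline
  effect size is the rank-biserial correlation, `2·U/(n₁n₂) − 1` from the
  Mann–Whitney U, signed positive when A exceeds B; it equals ±1 under
  complete separation, which is exactly the observed pattern for
  aerosacculitis (near-zero in heavy chickens). The point-biserial
  coefficient (Pearson correlation with the group indicator, A = 1) is
  computed alongside. The group indicator is the only dichotomised
  quantity; outcomes stay continuous.
* **Correlation**: Spearman rho with average-rank ties, pairwise over the
  seasonal-eligible causes. A constant series makes rho undefined for its
  pairs; those entries are NaN and labelled "undefined" — never coerced to
  zero. Strength bands on |rho|: ≥0.9 very high, 0.7–0.9 high, 0.5–0.7
  moderate, 0.3–0.5 low, <0.3 negligible.
* **Seasonal tests** run on the stage-one ratios with calendar month as
  the factor and years as replicates — the only replicate structure the
  two-stage construction admits. One-way ANOVA is followed by Tukey HSD
  (statsmodels); months with fewer than two replicate years are dropped
  with a warning, and an all-identical input short-circuits to "no pair
  significant" rather than a 0/0 F statistic. The per-month one-sample
  t test against 1 requires n ≥ 2 and positive sample variance; a
  zero-variance month raises a degenerate-sample error instead of
  reporting a spuriously extreme p.
* α = 0.05 throughout. No correction is applied across causes or
  variables beyond the within-cause Tukey adjustment; a Holm step-down
  helper is provided but off by default in reports.

## Synthetic generator

For month index `t` (0-based) in calendar month `m`, head counts `N_s`
are drawn Poisson around schedule means and each cause count is drawn
with mean `Σ_s N_s · p_{c,s} · season_c[m] · trend^t`. Noise is Poisson by
default — the minimal count model — with a negative-binomial option
(gamma-mixed Poisson, variance `μ + μ²/k`) for overdispersion
experiments. Seasonal 12-vectors are renormalized to arithmetic mean 1 on
construction so the injected multiplier *is* the ASI estimand when the
trend is flat; a strong trend biases within-year ratios upward late in the
calendar year, and the generator exposes `trend` precisely so that bias
can be measured rather than hidden.

The reference configuration encodes the study conditions of the
motivating series, fixed once from its published summaries: 131 months
(January 2009 – November 2019); ~5.9M head/month; turkeys ≈5% of head
until their phase-out (reduced in 2017, last slaughtered February 2018);
griller chickens replaced by heavy chickens in July 2017; per-species
per-head condemnation probabilities back-solved from the published group
means (≈7.0% of head condemned in turkey-era months, ≈10.1% in
heavy-chicken-only months, aerosacculitis concentrated in turkeys at 12.5%
per head vs 0.002% in heavy chickens); a July-peaking ascitic-syndrome
season (raw July multiplier 1.55) and a May–September aerosacculitis
trough; trend 1.001/month. Under this schedule the species-mix grouping
yields 110 A months and 21 B months.

What the generator does *not* emulate: serial autocorrelation beyond the
smooth trend, reporting artefacts (digit preference, batch corrections),
inspector-effort changes, and cross-cause count dependence beyond shared
head counts. Passing recovery tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to those real-data
features.

## Calibration experiments and problem sizes

The test suite and the acceptance script measure, at sizes chosen to keep
Monte-Carlo error well below the decision margins:

* **Seasonal recovery** — a random multiplier vector on an 11-year,
  1.5M-head/month, p = 0.005 single-cause Poisson series is recovered with
  max-abs error ≤ 0.05 (observed ≈ 0.006).
* **Type-I error** — 170 independent flat-null 11-year series × 12
  calendar-month tests = 2,040 one-sample tests; the rejection rate at
  α = 0.05 must lie in 0.05 ± 0.02 (observed ≈ 0.05–0.06 across seeds).
* **Power** — a July multiplier of 1.55 must yield Tukey-significant
  July-vs-each-of-January–June contrasts in ≥ 90 of 100 seeded series
  (observed 100/100).
* **Oracle agreement** — rank-biserial vs O(n·m) pair counting, Spearman
  vs rank-then-Pearson with hand-computed average ranks, ASI vs a naive
  double loop: 100 random instances each, agreement to 10⁻¹² (exact for
  ASI).
* **Tukey FWER** — ≤ 0.07 over 500 null replicates of a 6-month × 5-year
  design.

## Numerical and I/O choices

CSV dialect: comma-separated, UTF-8, '.' decimal, optional thousands
separators stripped on read; one wide row per month (condemnation counts
are not species-attributable, so a per-species long form cannot carry
them). Report CSVs round percents and indices to 2 d.p. and other
statistics to 3–4 d.p. with fixed formatting, making reruns byte
identical; full precision is always available through the library API.
Duplicate months and unregistered cause columns are hard errors;
validation failures name the row and column.

## Limitations

* Sampling variability of the published summary tables cannot be
  propagated: only their printed precision is available.
* ASI assumes the seasonal profile is stable across years; a trend or a
  composition breakpoint leaks into the profile (quantifiable via the
  generator's `trend` and schedule).
* Months are treated as exchangeable within and across years; no
  autocorrelation or overdispersion adjustment is made in the tests
  themselves.
* The species-mix grouping is derived strictly from head counts; months
  with turkey-only or griller-only slaughter (not observed in the
  motivating data) are deliberately left unclassified.
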