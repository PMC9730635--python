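# avicond

Surveillance analytics for poultry-slaughterhouse condemnation records.

At post-mortem inspection, official veterinarians condemn carcasses
(totally) or carcass parts (partially) and log the cause — contamination,
contusion/traumatic injury, dermatosis, aerosacculitis, ascitic syndrome,
and so on. Monthly tallies of these records, alongside the number of birds
slaughtered per species category (turkey, griller chicken, heavy chicken),
form a long count-rate time series that plant managers and inspection
services use to target training, equipment maintenance and seasonal
husbandry measures. `avicond` implements the statistics this kind of
monitoring relies on, for anyone analysing inspection-service spreadsheets
or similar abattoir surveillance data.

## The statistics

**Condemnation Occurrence Index (COI).** For a period with `c` condemnation
records (partial + total combined) and `N` birds slaughtered,

```
COI = 10^6 · c / N
```

i.e. condemnations per million head (the scale is configurable).

**Adjusted Seasonal Index (ASI).** A ratio-to-annual-mean seasonal profile,
built in two stages from the monthly COI series. Stage one removes year
level: each month's COI is divided by the arithmetic mean of that year's
usable monthly COIs, so every complete year's twelve ratios average to 1.
Stage two averages each calendar month's ratios across years:

```
ASI_m = (1/Y_m) · Σ_y  COI_{y,m} / mean_k(COI_{y,k})
```

ASI = 1 means "as expected for the year"; 1.63 means 63% above
expectation. Partial years use only the months present, and months flagged
as inconsistent are excluded throughout, reducing `Y_m` for their calendar
month.

**Inference.** Months are classified by species mix into group A (turkey
slaughtered alongside chicken) and group B (heavy chicken only), and
per-month percent condemnation ratios are compared by a Welch t test with
a rank-biserial effect size (2·AUC − 1 from the Mann–Whitney U; the
point-biserial coefficient is reported alongside). Cause co-movement is
summarised by a Spearman rank-correlation matrix graded on the
conventional strength bands (|rho| ≥ 0.9 very high, 0.7–0.9 high, 0.5–0.7
moderate, 0.3–0.5 low, otherwise negligible). Seasonal structure is tested
on the stage-one ratios by one-way ANOVA with calendar month as factor and
years as replicates, Tukey HSD pairwise contrasts, and a per-month
one-sample t test against 1.

**Synthetic data.** Because inspection-service spreadsheets are rarely
redistributable, the package ships a generator that draws monthly series
with the structure the analysis assumes: per-species head-count schedules
with a species-composition breakpoint, cause- and species-specific
per-head condemnation probabilities, calendar-month multiplicative
seasonality (renormalized to mean 1), a slow trend, and Poisson or
negative-binomial noise. Every statistical routine is validated by
parameter recovery against this generator.

## Worked example

```python
import avicond as av

ds = av.simulate_dataset(av.reference_config(seed=1))

share = av.period_coi(ds, scale=100)
print(f"overall condemnation share: {share:.2f}%")

cmp = av.compare_groups(ds, "aerosacculitis")
print(f"A: n={cmp.group_a.n} mean={cmp.group_a.mean:.3f}%  "
      f"B: n={cmp.group_b.n} mean={cmp.group_b.mean:.3f}%")
print(f"Welch p={cmp.p_value:.3g}  rank-biserial={cmp.rank_biserial:.3f}")

asi = av.compute_asi(av.coi_series(ds, "ascitic_syndrome"))
print("  ".join(f"{m}:{asi.asi[m]:.2f}" for m in sorted(asi.asi)))
```

prints

```
overall condemnation share: 7.80%
A: n=110 mean=0.712%  B: n=21 mean=0.002%
Welch p=6e-60  rank-biserial=1.000
1:0.65  2:0.68  3:0.80  4:0.64  5:0.67  6:0.89  7:1.57  8:1.45  9:1.36  10:1.26  11:1.02  12:1.01
```

The simulated 131-month series condemns 7.8% of head overall. Aerosacculitis
is concentrated in turkey-era months: group A averages 0.71% of head per
month while heavy-chicken-only months average 0.002%, a complete
separation (rank-biserial exactly 1). The ascitic-syndrome seasonal index
recovers the injected cold-season profile — July peaks at 1.57, i.e. 57%
above the annual expectation.

The same pipeline runs from the shell:

```bash
avicond simulate --seed 1 --out sim.csv
avicond report --input sim.csv --exclude 2017-06 --exclude 2019-12 --out report/
```

which writes `coi.csv`, `freq.csv`, `asi.csv`, `groups.csv`,
`correlations.csv`, `tukey.csv`, `asi_tests.csv`, the COI/ASI/heatmap
figures, and a run log.

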