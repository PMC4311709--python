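# rarepulse

Analyses for soil drying/rewetting experiments that link the **rare
biosphere** to pulses of ecosystem activity. When dry soil is rewetted,
dormant bacteria resuscitate within days, previously undetectable taxa can
come to dominate the community, and the soil emits a pulse of CO₂ (the
Birch effect). `rarepulse` implements the computational side of such a
study end to end, for microbial ecologists who have:

- paired dry/rewetted 16S OTU count tables from a factorial design
  (ecosystems × watering treatment × replicates),
- qPCR profiles across density-gradient fractions from H₂¹⁸O DNA
  stable-isotope probing (SIP),
- field sensor series of soil moisture and CO₂, and
- headspace trace-gas time courses (CO₂, CH₄, N₂O) from sealed microcosms.

A first-class synthetic-data generator emulates all four data types with
known ground truth — including a lognormal rank-abundance community with a
dormant seed-bank fraction — so every stage is testable at desk scale
without any sequencing downloads.

## What it computes

**Rare responders** (the core analysis). For each experimental unit both
samples are rarefied to a common depth; an OTU with rarefied count 0 in the
dry sample but > 0 in the paired rewetted sample is a *rare responder*. The
package reports the responders' share of taxa and of sequences, the
singleton/doubleton makeup of the shared pool, rank-abundance shifts,
*dominant* responders (relative recovery ≥ 1%, inclusive), and a
taxon-group × ecosystem recovery matrix. Because finite sequencing misses
taxa at random, this statistic has a nonzero null floor even with no
biological response; the package computes that floor analytically
(`expected_null_rare_otu_fraction`) and the classifier is validated against
simulation ground truth.

**SIP gradients.** From 16S copies across gradient fractions it selects the
max-sum contiguous fraction window (default width 2) as the DNA peak in the
dry (unlabelled) and rewetted (labelled) gradients, and reports the
buoyant-density shift range

  shift = [ρ_lab,min − ρ_unlab,max , ρ_lab,max − ρ_unlab,min],

calling isotope incorporation when the conservative edge exceeds a minimum
shift (default 0.01 g mL⁻¹).

**CO₂ pulse regression.** On a 12-h time step,

  CO₂(t) = β₀ + β₁·CO₂(t−1) + β₂·moisture(t) + β₃·moisture(t−1) + ε_t,

fitted by OLS with iterated Cochrane–Orcutt AR(1) correction of the
residuals (Newey–West errors available instead). Built statsmodels-style:
`PulseModel(series).fit()` returns a results object with estimates,
standard errors, t statistics, ρ, R² and `summary()`.

**Trace-gas budgets.** Headspace ppmv → µg element (C or N) via the ideal
gas law; net production per g soil is the sum of the signed 12-h
increments (negative = net consumption, as for CH₄ uptake); treatment ×
ecosystem effects via balanced two-way ANOVA and Tukey HSD with compact
letter display.

**Community turnover.** Rarefaction without replacement, observed richness,
Bray–Curtis dissimilarity (1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ)), and a from-scratch
two-factor PERMANOVA (Gower-centred matrix, sequential Type I SS, free or
within-stratum permutation) — verified against R `vegan::adonis2` and
classical pairwise-distance formulas.

## Worked example

```python
import rarepulse as rp
from rarepulse.responders import PairedSample, RareResponderReport, report_table

table, truth = rp.generate_paired_otu_tables(rp.SeedBankParams(seed=1))
reports = [RareResponderReport.from_pair(PairedSample.from_table(table, pid, seed=1))
           for pid in table.pair_ids()]
print(report_table(reports)[["ecosystem", "n_shared", "n_rewet_only",
                             "rare_otu_fraction", "rare_seq_fraction"]].head(4).round(3))
```

prints

```
        ecosystem  n_shared  n_rewet_only  rare_otu_fraction  rare_seq_fraction
pair_id
E1R1           E1        72           202              0.737              0.789
E1R2           E1        71           200              0.738              0.801
E1R3           E1        80           210              0.724              0.765
E2R1           E2        79           222              0.738              0.773
```

i.e. in each simulated unit roughly 70–74% of the OTUs detected after
rewetting were below detection in the paired dry sample — the signature of
seed-bank resuscitation (the generator's dormant fraction is 0.7 with
resuscitation probability 0.5 and strong growth of resuscitated taxa).

Fitting the pulse regression to a simulated 12-h sensor series:

```python
import numpy as np
series, coef = rp.generate_sensor_series(rp.SensorSimParams(
    duration_h=6000.0, step_h=12.0,
    rain_times_h=tuple(np.arange(48.0, 6000.0, 240.0)),
    noise_sd=20.0, seed=2))
print(rp.fit_pulse_model(series).summary())
```

```
Lagged moisture -> CO2 pulse regression
  correction: ar1   n_obs: 499   rho: +0.2905   iterations: 3
  R-squared (original scale): 0.9997   (transformed scale): 0.9995

  term                    coef     std err         t
  intercept           409.9099      7.9475     51.58
  co2_lag               0.5981      0.0021    284.23
  moisture          23178.8659     35.1222    659.95
  moisture_lag      -3832.6123     69.9107    -54.82
```

recovering the generating coefficients (+23 292 on current moisture,
−3 949 on lagged moisture) within a few percent: wetting stimulates
respiration immediately, and the pulse decays as the water drains.

## Command line

```sh
rarepulse all --seed 1 --out demo_out       # simulate + full pipeline
rarepulse pulse --config run.yaml --window-h 12 --correction ar1
rarepulse rare --threshold 0.01 --level family
```

`all` writes every intermediate (OTU TSVs, SIP verdicts, fit JSON, net
production, distance matrices, responder reports) plus a `manifest.json`
recording stages, seeds and parameters; reruns with the same config are
byte-identical.

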