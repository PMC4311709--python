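# Methods

This note documents the models implemented in `rarepulse`, the synthetic
data they are exercised on, the numerical choices made where the design was
genuinely open, and what the desk-scale tests do and do not establish about
real data.

## The rare-responder statistic

The operational definition of a rare responder is detection-based: an OTU
with rarefied count 0 in the dry sample of an experimental unit and > 0 in
the same unit's rewetted sample. Choices behind the implementation:

- **"Below detection" means a rarefied count of exactly 0.** Both samples
  of a pair are rarefied (random subsampling without replacement, via the
  multivariate hypergeometric distribution) to the pair's minimum total
  before classification, so dry and rewetted receive equal detection
  effort. Rarefaction depth for table-wide analyses defaults to the
  minimum sample total.
- **Fractions are computed per experimental unit and then averaged across
  replicates**, never pooled; pooling would weight deeper-sequenced units
  more and break the paired structure. Per-ecosystem summaries report mean
  ± SEM over replicates.
- **The statistic has a nonzero null floor.** With dry and rewetted samples
  drawn independently from the same composition p at depths D₁, D₂, an OTU
  is missed in a multinomial sample with probability (1 − pᵢ)^D, so the
  expected responder fraction is Σᵢ q₂ᵢ(1 − q₁ᵢ) / Σᵢ q₂ᵢ with
  q = 1 − (1 − p)^D. `expected_null_rare_otu_fraction` computes this floor;
  tests verify the no-seed-bank generator matches it within Monte-Carlo
  error. Any empirical responder fraction should be read against this
  floor, not against zero.
- **Dominance threshold**: relative recovery ≥ 1% of the rewetted sample's
  reads, inclusive at the boundary.
- **Rank ties** are broken by ascending OTU id — deterministic and
  auditable; undetected OTUs are flagged unranked rather than assigned a
  tied bottom rank.
- Open ambiguities resolved: per-replicate (not pooled) computation is the
  default, and dominant responders are collected across any unit, with the
  per-unit recoveries and ranks reported so a repeat-count criterion can be
  applied by the caller.

## Synthetic communities (what the generator emulates)

Each pair of a 4 × 2 × 3 factorial design (ecosystems × dry/rewetted ×
replicates) is generated as:

1. latent abundances: one lognormal(0, σ = 2) draw per taxon (n = 2000),
   multiplied by a per-ecosystem lognormal(0, 0.5) perturbation — the
   standard rank-abundance shape for soil communities, with compositional
   separation between ecosystems;
2. a dormant fraction (default 0.7) of taxa suppressed to 10⁻⁶ of their
   latent abundance in the dry state — *not* zero, so non-detection arises
   from sampling, as in real sequencing;
3. on rewetting, each dormant taxon independently resuscitates with
   probability 0.5 and its abundance is multiplied by a lognormal growth
   factor (median 2 × 10⁶, log-sd 1), returning it to — and typically
   beyond — the active range: resuscitated taxa are fast growers;
4. observed counts: one multinomial draw of 1500 reads per sample from the
   normalised abundances.

Random streams are keyed per pair identity (`SeedSequence(seed,
spawn_key=(ecosystem, replicate))`), so enlarging the design never perturbs
existing pairs, and identical seeds are bit-reproducible.

The free parameters (σ of the rank-abundance law, growth-factor law) were
fixed once so that the mean rare-responder OTU fraction across 20 seeds
(0.70, per-seed means 0.67–0.73) brackets the 69–74% range observed in
real rewetted soils. What the generator does **not** reproduce: with 700
resuscitated versus 600 active taxa at 1500 reads, responder reads dominate
the rewetted sample more than in field data, so the simulated rare
*sequence* share (~0.8) and pair Bray–Curtis turnover (~0.8) sit above the
~0.5–0.75 seen in real soils; the singleton/doubleton share of the shared
pool (~0.28) sits below. Passing tests therefore establish correctness of
the statistics and the qualitative resuscitation signature, not the exact
read-level composition of any real community. No PCR/chimera/read-level
noise is simulated; generation starts at OTU counts.

## SIP gradient model

Profiles are a Gaussian copy-number bump over a linear buoyant-density axis
(20 fractions of 235 µL; fraction 1 densest) with multiplicative lognormal
qPCR noise (CV 0.2 by default). Peak selection is a **fixed-width max-sum
window** (default 2 fractions, the number of representative fractions
typically pooled) rather than a model fit — simple, auditable, and
matching practice; ties go to the denser window, which is conservative
against false labelling calls. The density axis defaults (step 1/75 g mL⁻¹,
fraction 1 at 1.6928) place the unlabelled peak window on fractions 12–13
within 1.531–1.548 g mL⁻¹ and the labelled window on fractions 9–10 around
1.573–1.586 g mL⁻¹, i.e. a heavy-oxygen shift of ~0.027–0.053 g mL⁻¹. The
minimum shift for a positive incorporation call defaults to 0.01 g mL⁻¹:
real ¹⁸O shifts are ≥ ~0.026, so the default admits weaker labelling while
excluding gradient drift. qPCR efficiency and standard curves are out of
scope; input is copies per fraction.

## Pulse regression

The model is CO₂(t) = β₀ + β₁CO₂(t−1) + β₂m(t) + β₃m(t−1) + ε on a 12-h
step (sensor data are block-averaged over half-open windows, trailing
partial windows dropped; the first aggregated point contributes only its
lag). Moisture is volumetric; ppmv CO₂ per cm³ H₂O cm⁻³ soil is numerically
identical to per m³ m⁻³, so no unit conversion is applied.

Serially correlated residuals are handled by **iterated Cochrane–Orcutt**:
estimate ρ from the lag-1 residual autocorrelation, quasi-difference all
variables (losing one observation), refit, and repeat until |Δρ| < 10⁻⁶ or
50 sweeps (non-convergence returns the last iterate with a warning flag —
it occurs for pathological series such as permuted moisture). This is the
standard AR(1) remedy for sensor residuals; Newey–West (HAC) standard
errors on the plain OLS estimates are available as `correction="hac"`. A
numerically perfect fit (residual SS ≤ 10⁻¹⁶ of total) short-circuits to
ρ = 0, since rounding noise carries no autocorrelation information.

R² is reported on both scales because they answer different questions:
`rsquared` (original, undifferenced scale, from the final coefficients) is
comparable to a plain regression R²; `rsquared_transformed` is the fit of
the last quasi-differenced regression. A rank-deficient design from
constant moisture degrades gracefully to AR(1)-only predictions via the
pseudoinverse; only constant moisture *and* constant CO₂ is rejected as
unfittable.

## Trace-gas accounting

Headspace element mass: n = PV/RT (R = 0.0820574 L atm mol⁻¹ K⁻¹), species
moles = n × ppmv × 10⁻⁶, times atoms of element per molecule (1 C for CO₂
and CH₄; 2 N for N₂O) and atomic mass (12.011 / 14.007 g mol⁻¹). Net
production is the sum of the eight signed 12-h increments divided by soil
mass; increments may be negative (net consumption).

- **Headspace volume defaults to 37.7 mL**: a 40 mL vial minus ~2.3 mL
  displaced by 3 g of packed soil; it is configurable because the true
  headspace is rarely reported.
- **The ~2.5% of headspace withdrawn per sampling is not corrected for by
  default**; an optional correction adds back the element mass removed with
  each earlier sample. Both behaviours are exposed because published
  protocols typically ignore the withdrawal.
- Fold change is the raw signed ratio rewetted/dry (undefined at dry = 0);
  percentage framings of sign-flipping gases (e.g. "150% reduction" in CH₄)
  are left to the caller.
- Two-way ANOVA requires a complete, balanced design with ≥ 2 replicates
  per cell (the experiment's design is balanced; general unbalanced
  decompositions are out of scope). Zero residual variance with nonzero
  effects reports F = ∞, p = 0 rather than NaN. The compact letter display
  is a sweep over mean-ordered groups assigning one letter per maximal run
  of pairwise non-significant groups — valid for Tukey comparisons at equal
  cell sizes, where significance is monotone in the mean difference.

## Community turnover and PERMANOVA

Bray–Curtis is computed on rarefied counts; at equal depth, count and
relative-abundance versions coincide. The two-factor PERMANOVA partitions
the Gower-centred matrix G = −½ J D² J with **sequential (Type I) sums of
squares**, ecosystem entered before treatment (the blocking-like factor
first); each term's pseudo-F uses the full-model residual. Projections use
pseudoinverse hat matrices (dummy designs are rank deficient). Significance
uses free permutation of samples by default — the common default — with
restricted within-stratum permutation available because the design is
paired within ecosystems; p = (1 + #{F* ≥ F}) / (1 + n_perm), so p-values
live on {1/(n_perm+1), …, 1}. Since Bray–Curtis is non-Euclidean, G can
have negative eigenvalues and a term's SS can in principle be negative on
pathological inputs; values are reported as computed. The implementation is
tested against R `vegan::adonis2` (frozen values), classical
pairwise-distance formulas, and exhaustive relabeling enumeration on
8 samples.

## Problem sizes in the test suite

Desk-scale sizes keep every check sharp and fast: oracle equivalences run
on 6–24 samples and ≤ 30 taxa; null calibrations use 100 PERMANOVA runs
(99 permutations each) and 1000 ANOVA nulls; coefficient recovery uses 500
12-h steps; generator-calibration checks use the full default community
(2000 taxa, 24 samples) over 20 seeds. The whole suite runs in well under a
minute on one CPU.

## Known limitations

- The generator's read-level composition deviates from real rewetted soils
  as described above; its purpose is ground-truth testability, not
  field-realistic sequence shares.
- The sequential-SS PERMANOVA and free-permutation default are one of
  several defensible conventions; results for unbalanced or strongly
  non-Euclidean designs should be interpreted with the usual caution.
- The pulse model is moisture-only by design: no temperature response,
  sensor calibration, or diffusion physics.
- Per-OTU isotope incorporation is an experimental, not computational,
  claim: the package computes compositional statistics and density shifts,
  and makes no per-taxon labelling calls.
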