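# Methods

This note documents the models, conventions and design decisions behind
polarnet: what each stage assumes, why the defaults are what they are,
and what the synthetic-study generator does and does not emulate.

## Relative quantification (2^(−ΔΔCt))

The Livak method assumes perfect doubling per PCR cycle (amplification
efficiency 2 for targets and reference alike) and a reference gene whose
expression is stable across genotypes and treatments. Under those
assumptions, for each biological replicate

    ΔCt   = Ct_target − Ct_reference          (cycles)
    ΔΔCt  = ΔCt − mean(ΔCt | calibrator)      (cycles)
    fold  = 2^(−ΔΔCt)                         (dimensionless)

Conventions, stated because qPCR practice varies:

- **Technical replicates are averaged on the Ct scale before ΔCt**, the
  standard Livak order of operations. Averaging after exponentiation
  would bias fold changes upward through Jensen's inequality.
- **Calibrator = the same genotype's control-treatment mean ΔCt**, so a
  fold change reads "relative to this genotype's unstressed plants".
  Cross-genotype calibration would change the meaning of every reported
  induction.
- **Group summaries are arithmetic mean ± SD (n−1) of per-replicate fold
  changes across biological replicates.** The SD therefore reflects
  biological variation only; technical variation is absorbed in the
  Ct-scale averaging.
- Missing data: a technical replicate with missing Ct is dropped with a
  warning; a biological replicate missing the reference gene is excluded
  with a warning; a gene losing *all* technical replicates in a cell it
  was measured in is an error. Raw Ct values outside a plausibility
  window (default 5–40 cycles) are rejected.

Exact identities used as test anchors: calibrator-group fold changes
have geometric mean 1 (their ΔΔCt are centred by construction), fold
change is monotone decreasing in ΔΔCt, and the whole pipeline is
invariant to a constant Ct offset applied to targets and reference
alike.

Not implemented: efficiency-corrected (Pfaffl-style) quantification,
multi-reference normalisation, melt-curve QC.

## Trait statistics

Two-way fixed-effects ANOVA with genotype, treatment and their
interaction, on **balanced designs only**. On balanced data Type I/II/III
sums of squares coincide and least-squares means equal cell means, so
the classical decomposition is unambiguous; unbalanced tables are
rejected with guidance rather than silently re-weighted. Constant data
(zero residual variance, detected with a relative tolerance of 1e−12 on
the squared data scale) reports F as undefined (NaN) rather than 0 or
infinity.

Tukey HSD uses the studentized-range distribution with the pooled error
term of the full two-way model (Tukey–Kramer form of the standard
error). The compact letter display is built by insert-and-absorb: start
from one letter column containing every cell; each significantly
different pair splits the columns containing both members; columns
contained in others are absorbed; letters are assigned in
descending-mean order so the largest mean always carries "a". The
display is reflexive-consistent — two cells share a letter exactly when
the pairwise test does not separate them — and this property is enforced
by a reconstruction test.

Two comparison families are provided because figure-legend practice
differs: `within_genotype` (default) compares the two treatment cells
separately inside each genotype (letters independent between genotypes,
matching legends of the form "different between treatments per
genotype"); `all_cells` compares all four genotype × treatment cells
jointly.

Percent change is 100 × (control − stress)/control with a
half-away-from-zero integer rounding for the headline form; full
precision is kept in tables. It is scale-invariant and requires a
positive control mean.

## Trait–gene PCA

Observations are biological replicates of one genotype across both
treatments (n = 6 by default); variables are phenotypic traits plus
per-replicate gene fold changes. Columns are centred and scaled to unit
variance by default because the variables mix units; with scaling the
analysis is a correlation-matrix PCA, without it a covariance PCA (both
are checked against direct eigendecompositions). The default variable
panel contains ten traits (chlorophyll a/b, carotenoids, soluble
sugars, H2O2, MDA, SOD/POX/CAT activities, grain yield); proline and
peroxisome abundance are carried in the trait table and can be added
through the configurable variable list.

Determinism: every loading vector is oriented so that its
largest-magnitude entry is positive, fixing the SVD sign ambiguity.
Variance fractions are reported in percent over all components and sum
to 100; with n = 6 rows the matrix has rank ≤ 5 after centring, and
components in the null space carry (numerically) zero variance — their
directions are basis-dependent and should not be interpreted.

## Differential correlation networks

**Sample basis.** Correlations are computed within one genotype over all
biological replicates pooled across both treatments (n = 6 by default,
configurable to treatment means). Pooling across treatments means the
treatment contrast drives most of the variance, which is what makes
near-unity gene–trait correlations attainable at these sample sizes; the
basis is recorded in every correlation matrix.

**Scale.** Expression values entering the networks are per-replicate
fold changes 2^(−ΔΔCt) (a config switch allows −ΔΔCt, the log scale).

**Edge classification.** Strength tiers partition |r| with half-open
boundaries — strong iff |r| ≥ 0.75, medium iff 0.25 ≤ |r| < 0.75, weak
iff |r| < 0.25 — and the sign is carried separately. Tiers apply to the
magnitude, not the signed value: thresholding signed r would classify
every negative edge as weak. r exactly 0 is assigned "positive" by
convention, flagged, and never counted as a reversal partner.

**Comparison.** One comparison per unordered gene pair: a polarity
reversal is any sign change regardless of tier (a separate `robust` flag
requires both tiers ≥ medium, and both statistics are reported); tier
transitions are recorded as ordered pairs such as strong→medium.
Reversal counts are symmetric in the genotype order. No
multiple-testing correction is applied to correlation p-values; the
analysis is descriptive.

**Roles.** A deterministic cascade over per-gene metrics:

1. **hub** — reversal count ≥ θ_rev (default 3) AND tolerant-network
   connectivity (count of non-weak incident edges) ≥ θ_conn (default:
   the median connectivity) AND significantly up-regulated in the
   tolerant genotype (one-sided one-sample t-test of stress-replicate
   log2 fold changes against 0, α = 0.05);
2. **phenotypic switcher** (among non-hubs) — fraction of gene–trait
   correlations whose sign flips between genotypes ≥ θ_switch (default
   1.0, i.e. every measured trait);
3. **contextual responder** — the remainder.

The up-regulation condition is part of the hub definition because
reversal counts alone do not separate hubs from well-connected
down-regulated genes (a gene can match a hub's reversal count while
being suppressed under stress). Connectivity is evaluated in the
tolerant network, where the hub genes show their highest connectivity;
gene–gene edges only enter reversal counts (with 8 genes a fully
reversed hub has at most 7), while the gene–trait block is used solely
for switcher classification. Increasing θ_rev can only shrink the hub
set (tested as a monotonicity property).

## The synthetic-study generator

**What it emulates.** A 2 genotypes × 2 treatments × 3 biological × 3
technical replicate field study: 8 target genes plus a stable reference
gene (fixed Ct baseline 20; target baselines 23–27 cycles, inside the
5–40 window), and 12 phenotypic traits with units. Grain-yield means
are set to the published group values (770.33 → 389.79 g/m² tolerant,
633.45 → 273.25 g/m² susceptible), so the percent-change stage
reproduces the 49%/57% reductions in expectation.

**Generative model.** Per genotype, latent log2 expression is
`X = F @ L.T + noise`, where F holds *fixed* orthonormal factor scores
over the 6 replicates — the treatment contrast, then polynomial
replicate contrasts and their treatment interactions, all mean-zero with
unit sample SD — and L is the genotype's loading matrix. Because the
scores are deterministic, the noiseless correlation structure is fully
determined by L (`cov = L @ L.T`, positive semidefinite by
construction), and the treatment column of L fixes each gene's planted
stress log2 fold change. Ct values are `baseline − X` plus Gaussian
technical noise per technical replicate, so the quantification stage
inverts the construction exactly at zero noise. Traits respond to the
treatment contrast only (control mean + stress effect + Gaussian
noise), tying every gene–trait correlation sign to the sign of the
gene's treatment loading — a loading-sign flip between genotypes is
precisely a full trait-polarity reversal.

**Tolerant genotype: one factor.** Its loadings live on the treatment
axis alone (planted log2 fold changes: +2.17 for TaHSP70 = 4.5-fold,
+2.46 for TaPEX11.4 = 5.5-fold, +1.5 for TaCAT1, and −0.8…−1.2 for the
five down-regulated genes). Every noiseless gene–gene correlation is
then exactly ±1 — the strongly polarised, fully connected network.

**Susceptible genotype: five factors, by necessity.** The planted
topology requires three *different* per-hub reversal counts (6, 5 and
3). Under a single-factor structure, edge signs are products of
per-gene loading signs, so reversal counts can take at most two values
(k and 8−k for k flipped genes); three distinct counts force a
sign-*frustrated* pattern (triangles whose edge signs multiply to −1).
Frustration also bounds magnitudes: a frustrated triangle with common
magnitude ρ is a valid correlation matrix only for ρ ≤ 0.5, so the
susceptible network cannot be strong everywhere — consistent with its
fragmented, medium/weak character. Its loading matrix was constructed
once, offline, by constrained optimisation: unit loading directions
were sought so that the deterministic fold-change-scale correlation
matrix satisfies the planted sign pattern (reversal counts 6/5/3 for
TaCAT1/TaHSP70/TaPEX11.4, zero reversals for TaHSP90, stable
co-regulation among the five peripheral genes, full trait flips for
TaSOD and TaDRP5B) and the planted tier pattern (exactly four
strong→medium downgrades for TaPEX11.4), with the widest attainable
sign margins; the result is frozen as literal constants. Gene SDs of
roughly 1.4–1.9 log2 units keep those margins several noise standard
deviations wide.

**Noise defaults** are 0.1 (SD, log2 scale) for biological variation
and 0.1 (SD, Ct scale) for technical replicates — a plausible qPCR
regime in which the planted structure is recoverable but not trivially
so. Trait noise SDs are set so each deterministic stress effect is at
least ~7 SDs wide; this is a design requirement of the switcher
definition (a single trait whose response drowns in replicate noise
would make "every trait flips" unattainable at n = 6), not a claim
about field data. Under these conditions the pipeline recovers the
planted reversal counts in ≈97–98 of 100 seeded studies and the full
role partition in ≈95–97 of 100.

**Determinism.** One master seed feeds NumPy's `SeedSequence`, which is
split into per-genotype substreams (PCG64); identical seeds give
identical tables across runs and platforms. The packaged
`paper_like` fixture is the seed-7 realisation and is regenerated
byte-identically by the test suite.

**What it does not emulate.** Plate and batch effects, amplification
efficiencies ≠ 2, primer-dimer artefacts or melt-curve failures,
missing-data patterns, unbalanced designs, trait–trait residual
correlations beyond the shared treatment response, within-season
weather structure, or any calibration to the original study's raw
data (which report group-level summaries, not replicate values).
Passing the recovery tests therefore demonstrates correctness of the
estimation machinery under a known truth — not that real field data
would yield these networks.

## Problem sizes and tolerances

The test suite and the acceptance script use the study-sized design
throughout (6 replicates per genotype, 8 genes, 12 traits) and 100
seeded studies for recovery rates. Exact algebraic identities
(calibrator geometric mean, ANOVA sum-of-squares decomposition, PCA
reconstruction, correlation-oracle agreement) are asserted at 1e−8 to
1e−12; planted-value recovery at zero noise at 1e−9 relative; recovery
rates at ≥95% (reversal counts) and ≥90% (role partition).

## Known limitations

- The hub rule's up-regulation condition uses a t-test with n = 3; at
  realistic effect sizes this is decisive, but for marginal inductions
  the hub set becomes sensitive to α.
- Reversal counts have no significance calibration (no permutation
  test); they are descriptive statistics of two estimated networks, and
  at n = 6 weak planted edges (|r| < ~0.2) have materially unstable
  signs.
- The balanced-only ANOVA is a deliberate restriction; unbalanced field
  data need a modelling decision (Type II/III, mixed models) that the
  package refuses to make silently.
- Treatment-mean correlation bases (n = 2) are accepted by the API for
  completeness but are degenerate for inference; the replicate basis is
  the supported default.
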