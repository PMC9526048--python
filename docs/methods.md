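# Methods

This note documents the models, conventions and numerical choices behind
`rhoscape`, and what its synthetic study system does and does not emulate.

## Coordinates and containers

All internal coordinates are 0-based and end-exclusive, so every stored
interval satisfies `length == end - start`; this convention was chosen
because the published warm-spot catalog's printed lengths equal end − start
exactly (e.g. 12,638,263 − 12,637,749 = 514).  GFF3 input (1-based
inclusive) is converted on read (`start-1`, `end`); BED passes through.
Readers validate rather than repair: unsorted or overlapping intervals,
negative rates, malformed coordinates and unknown comparison labels raise
errors naming the file and line.  An `IntervalRateMap` holds ordered,
non-overlapping `[start, end)` pieces with constant ρ/bp, the shape of an
LD-based estimator's text output; the `mean` column is used as the point
estimate and the credible-interval columns are ignored.

## Windowing and unit conversion

Window means are coverage-weighted: a window's value is
Σ(ρᵢ·overlapᵢ)/Σ(overlapᵢ) over intersecting intervals, NaN when nothing
overlaps, so windowing conserves the bp-weighted total.  The last partial
window is kept.  ρ/bp is converted to cM/Mb by a single per-arm constant
k = total_cM / Σ(valueᵂ·windowᴹᵇ); the arm's genetic length is a user
input (default 50 cM, a typical long-arm value for *D. melanogaster*).  A
positive scaling cannot change ranks, so Spearman correlations commute with
the conversion to machine precision — a tested invariant.  The log
transform is ln(value + ε) with ε = 10⁻⁸, far below any plausible ρ/bp, so
zero-rate windows stay finite while ranks of representable values are
preserved.

## Wavelet statistics

Tracks are mean-imputed (missing windows take the observed mean, which
biases correlations toward zero — the conservative direction), truncated
to the first 2ⁿ observations (telomere-proximal end), and decomposed with
the unitary Haar filter pair ((a+b)/√2, (a−b)/√2) run to a single smooth
coefficient.  Unitarity gives exact energy conservation and orthogonality
of detail coefficients across scales, which is what licenses treating
per-scale statistics as independent.  Scale s carries 2ⁿ⁻ˢ coefficients
spanning bin·2ˢ bp (50 kb … with 25-kb bins).

Per-scale association uses Kendall's τ-b with the tie-corrected normal
approximation; scales with fewer than 4 coefficients are reported
undefined, and significance calls on fewer than 10 coefficients are
flagged low-power (with 512-bin arms this bounds the usable range near
1.6 Mb).  Per-scale regression is OLS with intercept of the target map's
details on the features' and other maps' details; coefficients are
reported as (estimate, sign, −log₁₀ p) with −log₁₀ p capped at 300, the
numerical ceiling for an exact fit.  Collinear designs are flagged
rank-deficient per scale rather than raising.

## Window-level comparison

Spearman's ρ between aligned tracks drops incomplete pairs listwise, takes
average ranks on ties, and uses the t approximation on n−2 df; Bonferroni
adjustment multiplies by a configurable family size (default 15 = 5 arms ×
3 populations, the shape of one published correlation table).  The one-way
ANOVA across populations treats windows as exchangeable observations,
which is anti-conservative under spatial autocorrelation; this is
documented, not corrected.  Tukey's HSD (Tukey–Kramer under unequal n) is
reported only when the omnibus p < 0.05.

## Warm spots

The arm background is the length-weighted mean ρ.  The scanner requires
*every* interval in a run to reach fold×background (the stricter of the
two possible readings; a run-average mode would be laxer), with ≥ by
default and a strict-inequality flag.  Runs below 500 bp are dropped; runs
above 7,000 bp are split greedily left-to-right at interval boundaries —
the published catalog contains two abutting entries (1,463 bp + 6,246 bp)
consistent with exactly this rule — and an oversized single interval is
cut at exactly 7,000 bp, the inclusive cap implied by a printed 7,000-bp
entry.  Gene annotation lists overlapping gene spans in genomic order,
appending "Intergenic" whenever part of the spot is uncovered; divergent
overlap attaches a comparison label on ≥ 1 bp intersection, rendered in
the fixed order "C vs W, C vs T, W vs T", with "None" for no overlap.

## The synthetic study system

The generator's defaults define the study conditions: three populations on
five 23-Mb arms (three 12.8-Mb arms in the `analysis/` drivers, chosen so
six dyadic scales retain usable coefficient counts while every driver runs
in seconds), 25-kb bins, SNP density 0.001/bp matching the Watterson-θ
scale of the sequenced populations, background ρ = 0.01/bp.

Log-rate tracks are built by *inverse* orthonormal Haar synthesis: at scale
s the two populations' detail coefficients are
d = √w_s·z_shared + √(1−w_s)·z_pop with independent standard normals, so
the per-scale correlation has expectation w_s exactly; scales coarser than
the configured six are fully shared, emulating broad-scale conservation.
The default weights (0.3 … 0.8, fine to broad) encode fine-scale
divergence with broad-scale conservation.  Because the field is synthesized
in log space and exponentiated, the downstream log transform recovers a
near-Gaussian field, and Kendall's τ between Gaussian details with Pearson
correlation w has expectation (2/π)·arcsin(w) — the value the drivers
print alongside the estimates.  The field is scaled to standard deviation
`log_sd` = 0.5 in log units: realistic smooth heterogeneity under which a
10-fold exceedance of the arm mean essentially never arises from the
background, so every warm spot in a synthetic map is an injected one.

Interval maps place SNPs as a Poisson process, assign each inter-SNP
interval the rate of the bin covering its midpoint, and overwrite intervals
inside configured warm spots with fold × arm background; spot boundaries
are forced onto SNP positions so exact-boundary recovery is well defined.
Diversity is a linear blend α·standardized(rate) + √(1−α²)·noise mapped
linearly onto a π-like positive scale (expected Pearson correlation α,
rank correlation exactly 1 at α = 1); gene content is an independent
logistic field in [0,1]; read depth is positive and weakly coupled to
diversity.  Divergent-region sets cover exactly round(fraction·n_spots)
spots with 100-kb-aligned intervals (trimmed so they never touch an
unselected spot), plus background intervals placed avoiding all spots.
Randomness is drawn from named substreams of a single seed, so any stage
can be regenerated independently and identical configurations produce
byte-identical files.

What the generator does **not** emulate: coalescent noise and estimator
error in the rate maps (maps are deterministic given the field), real gene
structure and exon composition, demography, or selection.  Passing tests
therefore demonstrate the correctness of the downstream statistics and
bookkeeping under known structure, not the behaviour of LD-based
estimation on real sequence data.

## Design choices on genuinely open points

* Adjacent equal-rate intervals in input maps are preserved, not merged.
* Bonferroni family size is a parameter; the default mirrors one table.
* Truncation keeps the first 2ⁿ observations; centered truncation is a
  switchable alternative.
* Read depth enters the per-scale linear models as a covariate throughout,
  treating it as a global sequencing-bias control rather than a
  diversity-only adjustment.
* Empirical-map alignment assumes identical window start coordinates.
* In synthetic pipeline runs the reference cM/Mb map is the
  cross-population mean track (a synthetic stand-in for an externally
  measured map), and injected warm spots are partitioned round-robin
  across populations so each spot belongs to exactly one population's map.

## Problem sizes

The test suite and acceptance script use 4,096-bin arms for weight
recovery (20 replicate seeds per weight), 2-Mb constant-background arms
for the 100-arm warm-spot recovery study, 500 random maps for the
scanner-vs-oracle equivalence, 1,000 random series (up to length 4,096)
for the transform guarantees, and 6.4-Mb three-arm runs for the end-to-end
pipeline checks; together they complete in well under a minute.
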