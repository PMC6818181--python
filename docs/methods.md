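# Methods

This note documents the models, rules and numerical choices behind
`warburgph`, roughly in pipeline order, plus what the synthetic-data
generator does and does not emulate.

## Data model

Expression travels as genes × samples matrices on **log2 scale**
(log2-transformed normalized FPKM for RNA-seq-like data, normalized log
intensity for microarray-like data).  Operations that need linear scale
(fold-change ratios, the PDHB/PKM flux proxy) de-log explicitly with
2^x.  Missing values are rejected on read rather than imputed.  Each
sample carries exactly one label, `case` or `control`; a `paired` flag
marks matched designs.

## Expressed-gene threshold

Pooled log2 expression over all genes and samples of a dataset is
bimodal: a low mode of silent genes and a high mode of expressed genes.
The cut is the minimum of a Gaussian kernel density estimate (Silverman
bandwidth, 512-point grid spanning the data range) between the two
highest local maxima.  A gene at or below the cut in both groups is
called not expressed and excluded from testing.  Unimodal data raise
`NoValleyError`; callers may supply a manual threshold.  The estimator
is deliberately simple — one threshold per dataset (cases and controls
pooled), no per-sample thresholds — and is invariant to gene/sample
order because values are pooled.  At the canonical mixture
(equal-weight N(0,1) + N(6,1), the simulator's default modes) the
analytic density minimum is 3.0 and the detector recovers it within
±0.1 at n = 5000.

For microarray-like inputs keyed by probes, `collapse_probes` keeps, per
gene, the probe with the highest mean expression across all samples
(ties break to the lexicographically smallest probe id) and carries the
retained row over bit-exactly.

## Differential expression

Case vs control per gene with the Wilcoxon rank-sum (Mann–Whitney) test;
the signed-rank test is applied only when the design is declared paired
with equal group sizes, since signed-rank is undefined otherwise.  For
a total sample count ≤ 12 without ties the p-value is exact (and is
pinned against a full-enumeration oracle in the tests); larger or tied
problems use the tie-corrected normal approximation.  A fully tied gene
returns p = 1.  Fold change defaults to 2^(difference of log2 group
means); ratio-of-linear-means is available as a sensitivity option.
FDR is Benjamini–Hochberg across tested genes per dataset.

Two categorical tiers are derived per gene:

* **DEG call** — up/down when FC > 1.3 (or < 1/1.3) with BH-FDR < 0.01;
* **heatmap call** — up/down when log2FC > 0.6 (< −0.6), the coarser
  tier used for the transporter-panel summaries.

## Transporter panel and acidification score

The panel ships as an editable TSV (`data/transporter_panel.tsv`):
six acid loaders (SLC4A1AP, SLC4A2, SLC4A3, SLC26A6, ATP6V0B, ATP6V0C),
seven acid extruders (SLC4A4, SLC4A9, SLC9A2/3/4/9, SLC26A9) and the two
lactate exporters SLC16A1/3.  Excluded family members are retained with
their reasons (multi-compartment localization, absent expression,
non-bicarbonate function, …).  ATP6V0B and ATP6V0C encode subunits of
one V-ATPase complex and carry a single expression signal; both stay in
the panel, so a fully concordant dataset scores ±13.

The acidification score is an integer tally over heatmap calls,
`(#loaders up + #extruders down) − (#loaders down + #extruders up)`,
antisymmetric under swapping every call.  The lactate exporters never
contribute: they are proton-gradient-driven and cannot by themselves
reverse the intra/extracellular pH gradient, and their regulation is
assessed separately.  The score is an artifact-level surrogate for a
qualitative argument; its sign, not its magnitude, is the readout.

## Warburg classifier

Criterion (i): FC(LDHA) > 2 or FC(LDHB) > 2, **and** FC(SLC16A1) > 2 or
FC(SLC16A3) > 2, with FC computed from log2 group means.  Criterion
(ii): the median per-sample linear-scale PDHB/PKM ratio is strictly
lower in cases than controls.  The verdict is the conjunction.  Design
choices: "decreases" is operationalized as a strict decrease of the
median (an optional rank-sum significance gate is off by default, since
no test is inherent to the rule); ratios are taken per sample on linear
scale (a ratio of logs is not a flux proxy), with ratio-of-group-means
as a switch.  Samples with zero linear PKM are excluded from the ratio
and counted.  Both criteria are scale-free, so the verdict is invariant
to any common rescaling of linear expression.

## Gene-set correlation statistics

**PC regression.**  The set's samples × genes submatrix is centered
per gene and decomposed by SVD.  If PC1+PC2 explain ≥ 75% of the
variance, the query gene is regressed on them by least squares and the
fit is summarized by R² with an F-test p (the F statistic degenerates
to p = 0 at an exact fit).  A rank-1 set drops the zero PC2 column.
Querying a gene inside its own set is an error.

**Overlap test** (the fallback when the variance gate fails).  The query
gene's Pearson correlation with every background gene is computed
(vectorized, t-distribution p-values), significant genes are selected by
BH at α = 0.01, and the overlap m of the n selected genes with the
M-gene set is scored by the upper hypergeometric tail
P = 1 − Σ_{i=0}^{m−1} C(M,i)C(N−M,n−i)/C(N,n).  The overlap is the
*intersection* of the selection with the set — the tail is only defined
for m ≤ min(n, M).  An empty selection reports P = 1 with a degenerate
flag.  The same tail, against a default background of N = 20,000 genes,
drives generic GMT enrichment with BH q-values across the library and
top-k (default 100) selection.

**Principal-curve correlation.**  Each set's sample cloud is summarized
by arc-length projections onto a one-dimensional principal curve fitted
by Hastie–Stuetzle-style iteration: initialize the parameter from PC1,
lowess-smooth each coordinate against it (frac 0.6, no robustness
iterations), re-project samples onto the smoothed polyline, and repeat
until the mean relative projection displacement falls below 1e-6, stops
shrinking, or 100 iterations pass.  The stagnation stop matters: the
projection–smoothing iteration typically settles into a small
oscillation around its fixed point rather than converging through the
tolerance, and stopping at the first non-improving step keeps the
procedure fast and exactly mirror-symmetric (an antithetic copy of a
cloud yields the reversed projections, hence PCC = −1 bit-for-bit).
Curve orientation is fixed by positive correlation with the set's
per-sample mean expression.  Shared genes are removed from both sets
before fitting; the report carries PCC(DP₁, DP₂) and its two-sided
Pearson p.  Under independence the nominal p is well calibrated (null
false-positive rate ≈ 0.04 at p < 0.05 in the acceptance simulations).

## Fenton criterion

Each reaction side is summarized by the first principal component of its
standardized marker submatrix, oriented to correlate positively with the
set's mean expression; standardization makes the score invariant to
rescaling any single gene.  The product side defaults to a minimal
proteasome set (PSMA1/2, PSMB1/2, PSMC1, PSMD1 — users should supply
their full PSM list); the substrate side pools the H₂O₂ markers (TXN,
TXN2, GCLC, GCLM) and iron-uptake markers (TFRC, TFR2), plus a
user-supplied superoxide set — no superoxide default exists because no
canonical transcriptomic O₂·⁻ marker panel does, and its absence is
flagged in the verdict.  Marker sets must be pairwise disjoint.  The
dataset is called Fenton-positive when the Pearson correlation of the
two scores is positive with two-sided p < 0.01.  Requiring a *positive*
r makes the test effectively one-sided, so the realized type-I error
runs at about half the nominal level.  The companion coupling table
reports each panel transporter's Pearson r against the product-side
score, partitioned by role.

## Proton energetics

The ledger fixes, per ATP: respiration synthesis consumes 1 H⁺,
glycolytic synthesis is neutral with 1 lactate, hydrolysis releases
1 H⁺.  Hence glycolytic synthesis + hydrolysis = +1 H⁺/ATP and
respiratory synthesis + hydrolysis = 0 — integers, additive in the ATP
count.  The closed-form budget multiplies the free-proton concentration
change (mol/L) by cell volume (μm³, converted at 10⁻¹⁵ L/μm³), the
buffering coefficient (a dimensionless amplification of the free-proton
change — the conventional value 2×10⁵ for the 6.8–7.4 range carries no
units) and Avogadro's number, fixed at 6.02×10²³ rather than the CODATA
value so the canonical arithmetic reproduces exactly: pH 6.8 → 7.4 at
100 μm³ gives 1.4289×10⁹ protons, equivalently ATPs, ≈ 4.76% of the
3×10¹⁰ ATPs (6×10⁹ nucleotides × 5 ATP/nt) a genome's synthesis costs.
The budget is linear in volume and buffer and antisymmetric in the pH
endpoints (a negative count is returned with an "acidify" flag).

## Time-course segmentation

An activation course sampled at 19 points (20-minute spacing) drops the
time-zero point — it precedes activation — leaving 18 points averaged
into six consecutive triples T0..T5; any other non-divisible count is an
error rather than silently trimmed.  Segment averaging commutes with
gene-wise affine transforms.  Trend calls: rising/falling at Spearman
|ρ| ≥ 0.8 against segment index, peak-then-decline when the maximum is
interior with both flanks monotone, else flat.  The |ρ| ≥ 0.8 cut is an
artifact-level choice (the source designs describe trends verbally);
reversing a profile swaps rising and falling.  One pre-averaged value
per timepoint is assumed.

## Synthetic data

The generator draws each gene's log2 values iid N(μ, σ²) per sample with
a silent mode (default N(0,1)) for a configurable fraction of unnamed
genes and an expressed mode (default N(6,1)) otherwise, so the pooled
marginal is exactly the two-component mixture the threshold detector
assumes, with realistic within-group spread (σ = 1 on log2 scale).
Fold changes are planted as additive log2 shifts on case samples.
Latent links add a shared standard-normal factor with loading √ρ·σ to
every member of the linked groups (sign-flipped on the second group for
negative ρ), giving pairwise correlation ρ between — and within — linked
groups while preserving each marginal.  Named genes (planted, linked or
trending) are never silenced.  Time courses are linear log2 ramps
(amplitude 2, peak-then-decline peaking at the 60% mark) plus iid noise
(sd 0.25 by default; 0 gives exact trajectories).  Everything is
deterministic given the spec's seed.

What the generator does **not** emulate: count noise and library-size
effects, probe-level microarray artifacts, gene–gene correlation beyond
the planted factors, tumor purity, batch structure, or heavy-tailed
expression.  Passing tests therefore demonstrate that the procedures
recover planted structure under their own distributional assumptions —
not that those assumptions hold in any particular real dataset.

Three canonical scenarios pin the study conditions used by the examples,
tests and acceptance script, each at n = 100 case / 100 control and 200
genes: **cancer-like** (LDHA ×4, SLC16A1 ×3, PDHB ×0.5, all six loaders
×2, all seven extruders ×0.5, PSM↔substrate-marker latent link at
ρ = 0.8 that also loads the acid loaders), **NPC-like** (same Warburg
fold changes, loaders ×0.5, extruders flat, no Fenton link) and
**null** (all analysis genes expressed, nothing planted).

## Problem sizes and calibration checks

The simulation studies run at the scenario sizes above: Warburg
recovery and null rates over 100 seeded replicates each; Fenton type-I
error over 200 null replicates and power over 100 at ρ = 0.8 (40-gene,
100-sample datasets); threshold recovery over 50 replicates of 5000
pooled values; principal-curve null calibration over 200–300 replicates
of independent 3-gene sets across 200 samples.  Replicate counts were
chosen for Monte-Carlo precision of the reported rates at these sizes.
The enumeration oracles cover every hypergeometric configuration with
N ≤ 12 and every rank-sum split of ≤ 12 samples.

## Known limitations

* The Fenton marker aggregation (oriented PC1) is a minimal faithful
  estimator; it does not reproduce any upstream model mapping expression
  to molecular quantities, only the correlation criterion between sides.
* The ATP6V0B/0C plasma-membrane expression is used as observed; no
  deconvolution of multi-compartment V-ATPase expression is attempted.
* The acidification score weighs every transporter equally, ignoring
  kinetics (Vmax differences of orders of magnitude between V-ATPase and
  the lactate exporters are argued qualitatively, not modeled).
* Principal curves use a fixed lowess span (0.6); very curved or very
  small clouds may need a different span, exposed as a parameter.
* The proton budget is static stoichiometry — no dynamic pH simulation,
  transporter kinetics, or compartment exchange.
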