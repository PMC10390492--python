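# Methods

This note documents the statistical procedures, the defaults and why they
hold, the synthetic-data generator's design, numerical conventions, and known
limitations. Notation: `n` spots, cell-type weight matrix `W` (spots × types,
rows on the probability simplex), expression matrix `X` (genes ×
observations), regulon activity matrix `A` (spots × regulons, values in
[0, 1]).

## Normalization

Raw counts are library-size normalized and log-transformed:
`x' = ln(1 + x / total(obs) × scale_factor)` with `scale_factor = 10,000`.
Observations with zero total counts are rejected with their ids listed. The
transform is monotone within an observation and invariant to multiplying an
observation's counts by a constant; both properties are under test. Optional
spot QC (minimum detected genes, maximum mitochondrial fraction) is provided
as a preprocessing helper but is not part of any pipeline stage.

## Colocalization network

Colocalization of a type pair is the Pearson correlation of their weight
columns over all spots (within-spot colocalization only; no spatial-lag or
neighborhood variant). The p-value uses the two-sided t approximation
`t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of freedom — the standard test
for a correlation coefficient; the source procedure names only an "adjusted
p-value", so Benjamini–Hochberg over all unordered type pairs with finite
correlation is used, and the family is configurable. An edge requires
`PCC > 0.06` *and* `q < 0.05`, both strict.

The PCC cutoff is not decorative: deconvolution weights are compositional
(rows sum to 1), so under a structureless null all pairwise correlations sit
near `−1/(k−1)` and are "significant" at any reasonable sample size. The
positive-PCC side of the rule is what makes the stage calibrated; the null
calibration test therefore counts retained *edges*, not small q-values alone.

Weight binarization defaults to `weight ≥ 0.1` (boundary inclusive) when no
externally supplied boolean occupancy table is given; an external table is
aligned by spot and type ids and passed through. The 0.1 default makes the
stage self-contained where upstream "confident call" tables are unavailable.

## Ligand–receptor co-expression and spatial enrichment

Per spot, `R_LR = L(exp) · R(exp)`. Multi-subunit sides aggregate by
geometric mean (zero if any subunit is zero), mirroring the convention of the
curated ligand–receptor resource this schema models; an arithmetic-min option
exists. Pairs with missing subunit genes are skipped with a logged warning.

For each colocalization edge (A, B) and each pair, spots are classified by
`X = occ(A) ∧ occ(B)` and `Y = (R_LR > 0)` into a 2×2 table
`a = |X∧Y|, b = |X∧¬Y|, c = |¬X∧Y|, d = |¬X∧¬Y|`. The test is the one-sided
(enrichment) Fisher exact test, `p = P(hypergeometric ≥ a)` with margins
fixed — the procedure tests enrichment, so the "greater" side is fixed by
design. BH runs pooled over all (edge, pair) rows; per-edge correction is a
documented alternative. Each (edge, pair) row gets its own table (the
per-row reading of the contingency construction, since co-expressed pairs
are binarized individually). Odds ratio is `ad/bc`, `+inf` when `bc = 0`
with `ad > 0`, NaN when both products vanish. Co-expression binarization is
strictly `R_LR > 0`; an optional quantile threshold for deeply sequenced
data defaults off.

## Communication probability and the final filter

Full mass-action communication frameworks add cofactor modulation, trimean
summaries and population-size effects; this package deliberately implements a
minimal, saturating ligand×receptor score

```
prob(s, r, pair) = L_s·R_r / (kh + L_s·R_r),   kh = 0.5,
```

where `L_s` is the geometric mean over ligand subunits of the sender's mean
log-normalized expression (arithmetic mean per type; trimean offered as an
option) and `R_r` likewise for the receiver. The two testable essentials are
preserved: monotonicity in both sides with saturation controlled by `kh`, and
a one-sided permutation test. Significance is
`p = (1 + #{prob* ≥ prob_obs}) / (n_perm + 1)` over `n_perm = 1000` global
label shuffles (global, not within-batch, matching the exchangeability
assumption of the test); `p ≥ 1/(n_perm+1)` by construction and rows with
zero observed probability get `p = 1` automatically because every permuted
score ties.

The communication table covers all ordered sender→receiver pairs. The final
filter retains a directed row iff its unordered pair is a network edge, the
pair is enriched on that edge, and the permutation test is significant; both
directions of an enriched unordered edge are evaluated, since enrichment is
undirected while communication is not.

## Regulon activity, specificity, and modules

**Recovery-curve AUC.** Per observation, genes are ranked by descending
expression; the recovery curve counts gene-set members among the top ranks up
to `max_rank = ceil(top_frac × n_genes)` (`top_frac = 0.05`, configurable —
the conventional default of the recovery-AUC method); the score is the area
under the step curve divided by its maximum possible area, hence in [0, 1],
1 when the set occupies the top ranks and 0 when no member appears in the
window. Sparse spot data has massive zero ties, so ties are broken by one
seeded random permutation shared across observations — this makes the score a
deterministic function of (matrix, set, top_frac, seed) and leaves it
invariant under any strictly monotone transform of expression.

**RSS.** A regulon's activity column normalized to sum 1 is compared with a
domain's indicator normalized to sum 1 via Jensen–Shannon divergence with
base-2 logarithms (so JSD ∈ [0, 1]), and `RSS = 1 − sqrt(JSD)` — the
established similarity conversion of the RSS method. RSS is 1 exactly on an
indicator match and invariant to positive scaling of the activity column;
zero-sum columns yield NaN and are flagged.

**CSI.** With `P` the pairwise Pearson correlation of activity columns,
`CSI(A,B) = |{C : P(A,C) < P(A,B) ∧ P(B,C) < P(A,B)}| / N` over all `N`
regulons, strict inequalities, no subtracted margin (a margin option `δ`
exists because parts of the CSI literature use `δ = 0.05`). A and B never
count themselves since `P(A,A) = 1`. Constant columns are excluded with a
log entry.

**Modules.** Agglomerative clustering of CSI rows, Euclidean distance, Ward
linkage by default (the source procedure names only hierarchical clustering
with Euclidean distance; Ward is the variance-minimizing standard), cut at
`n_modules = 7` by default — a data-dependent choice, exposed in config. A
module's mean activity per spot is the arithmetic mean of its members'
columns. The co-activation network keeps pairs with `CSI > 0.85`, strict.

## Axis patterning

**Section patterns.** All contiguous runs of the ordered section list with
length in `[2, n_sections − 1]`: singletons and the full run are excluded —
the only bounds consistent with 35 combinations over nine sections
(`Σ_{ℓ=2}^{8} (9 − ℓ + 1) = 35`); both bounds are parameters. Gene selection
correlates each candidate gene with each pattern's indicator broadcast to
spots (every spot inherits its section's 0/1 value; a section-mean variant is
available but spot-level uses all data) and takes the union of the top-20
genes per pattern; constant genes are skipped with a log entry, and top-k
ranking breaks ties deterministically by gene id.

**Axis regulons.** Anterior–posterior: correlation of each activity column
with a supplied pseudo-space ordering (pseudo-space is consumed, never
computed; when absent, section order with within-section y is the documented
fallback); selected iff `|PCC| > 1.5 × SD(all PCCs)` *and* max activity
`> 0.2`, both strict. Dorsal–ventral: one-vs-rest rank-sum per region on
activity with BH pooled over all tests plus the same max-activity filter.

**Rank-sum test.** Exact enumeration when the combined sample is ≤ 12 with no
ties, otherwise the normal approximation with tie and continuity correction;
two-sided by default. All-identical samples return p = 1 (the degenerate
approximation limit).

**Region scores and binarization.** Region gene-set activity uses the
recovery AUC. Binarization `zscore` zeroes scores with column z below 2.5
(zero-variance columns are an error); `bimodal` zeroes scores below the
midpoint of the two group means of the 1-D split minimizing within-group sum
of squares — a surrogate for an upstream tool's unspecified binary assignment
threshold; a degenerate column passes through with a warning.

**Module score and cell cycle.** Genes are binned into 24 equal-size bins by
mean expression; per signature gene, 100 control genes are sampled with
replacement from its bin (seeded) and pooled as a unique control set;
score = mean(signature) − mean(controls) per spot. Pooling the *unique*
sampled genes makes the score exactly 0 when a bin contains only the
signature itself. Phase call: G1 when both S and G2M scores are ≤ 0,
otherwise the larger score's phase.

## Synthetic data generator

The generator emulates the structure the pipeline detects, at desk scale, and
is the study condition for every calibration and recovery test.

- **Geometry.** `n_sections = 3` sections of a 12×12 grid (432 spots) by
  default; the gradient preset uses 9 sections of 10×10 (900 spots) so that
  all 35 section patterns exist. Domains are equal-width vertical bands
  spanning all sections, one per planted type pair plus a background band.
- **Weights.** Dirichlet per spot (respecting the simplex constraint of
  deconvolution outputs). Inside its domain a planted pair's two
  concentration parameters get a boost `10 × effect_size × u` with a shared
  per-spot intensity `u ~ U(0.5, 1.5)`. The shared intensity matters: with a
  fixed symmetric boost the pair's weights would be compositionally
  anti-correlated within the domain; shared intensity produces the positive
  co-variation colocalized types show in real deconvolution output.
- **Counts.** Negative binomial with shape 10 (overdispersed, so Fisher and
  permutation calibration are tested under realistic variance), on log-normal
  per-gene baselines with per-spot log-normal noise (sd 0.25). Planted
  ligand/receptor genes sit on a low baseline (mean 0.2) and are multiplied
  by `1 + 10 × effect_size × w` of the sender/receiver weight, so
  co-expression concentrates where the planted pair colocalizes; decoy
  ligand/receptor genes sit at a moderate baseline (mean 2.0) everywhere,
  independent of any domain.
- **Reference cells.** Per-type negative-binomial counts on the same
  baselines, with planted ligands elevated `(1 + 4 × effect_size)`-fold in
  their sender type and receptors in their receiver type.
- **Gradients.** The gradient preset plants *two* monotone ramp genes per
  contiguous section interval (70 genes over nine sections, ramp gain
  `8 × effect_size`) among ~290 flat decoys. Two per interval is a designed
  property of the fixture: the selection rule is a union of top-k lists, so
  the planted set must be rich enough to saturate each pattern's top-20 for
  decoy rejection to measure the method rather than list-length arithmetic.
- **Regulon activity.** Planted regulons are `baseline + specificity` inside
  their domain and `baseline` outside plus Gaussian noise, clipped to [0, 1];
  gradient regulons ramp linearly along the pseudo-order with alternating
  sign among flat decoys; two-block fixtures drive each block with an
  independent latent factor.
- `effect_size = 0` is the null: planted and decoy structure become
  statistically indistinguishable, which is what the calibration tests rely
  on. All generators are pure functions of (parameters, seed).

What the generator does **not** emulate: histology, spatial autocorrelation
beyond block-domain structure, transcriptome-wide gene–gene correlation,
batch effects, segmentation artifacts, or realistic marker-gene overlap
between cell types. Passing recovery tests therefore demonstrate correctness
of the statistics under the planted model, not performance on tissue data.

## Problem sizes used in tests and the acceptance script

Calibration experiments use 100 simulated data sets (null permutation
calibration: 100 × 50 pairs at 200 permutations; Fisher/rank-sum nulls by
direct construction); recovery experiments use 25–50 seeds at the default
atlas size; the end-to-end recovery runs 25 full pipeline executions at the
default 1000 permutations. These sizes give binomial standard errors a few
times smaller than the margins being tested while keeping a full run around
a minute on one CPU.

## Numerical conventions and degenerate inputs

- Strict inequalities everywhere a threshold is printed (`PCC > 0.06`,
  `CSI > 0.85`, `max RAS > 0.2`); boundary values are excluded, and weight
  binarization is the one documented `≥` boundary.
- Zero-variance columns: excluded and flagged (correlation, CSI), an error
  where silence would be misleading (z-score binarization).
- Constant columns are detected by `max == min`, not by a floating-point SD
  threshold.
- Fisher degenerate table (all zeros) has p = 1; odds-ratio conventions as
  above.
- BH families: all unordered type pairs (colocalization), all (edge, pair)
  rows pooled (enrichment), all (gene/regulon, region) tests pooled (axis);
  each documented where configurable.
- Duplicate feature ids on read are disambiguated deterministically with
  `.1`, `.2`, … suffixes; gene matching is exact string match after
  whitespace strip, with no symbol aliasing — mismatches are reported rather
  than silently mapped.

## Known limitations

- The communication score is a documented simplification; absolute `prob`
  values are not comparable with full-featured frameworks, only the
  monotonicity and the permutation p are.
- Colocalization is within-spot only; neighboring-spot signaling is invisible
  by construction.
- The BH family choices above are one reading of an ambiguous procedure;
  alternative families are configurable but change q-values.
- Pseudo-space ordering and regulon gene sets are inputs; trajectory
  inference and regulatory-network inference are out of scope.
- The recovery-AUC tie-break injects a seeded randomization; scores on
  heavily tied (very sparse) data depend on that seed at the margin.
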