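# Methods

`ctbulk` implements a cell-type-resolved comparison of two patient groups
(group A, modeling brain metastases; group B, modeling extracranial
metastases) from sparse single-nucleus RNA-seq, together with a synthetic
cohort generator that reproduces the statistical structure of such a study
so that every stage is testable without any data download. This note
records the models, the numerical choices, and the reasoning behind the
design decisions that were genuinely open.

## Pipeline model

The analysis chain is: cell QC → library-size log-normalization →
(optional) per-patient centering → **imputation masking** → pseudobulk
aggregation → per-cell-type moderated-t differential expression →
correlation homogeneity analysis → signature clustering with bootstrap
support → missing-tolerant PCA → ranked-list enrichment.

**Imputation masking.** After integration an expression matrix is dense,
but every entry whose raw count was zero is an artificial value. `mask_imputed`
marks exactly those entries missing (mask ≡ raw == 0), so downstream
statistics consume only measured signal. All later stages are
missing-aware: pseudobulk means run over observed cells, Pearson
correlations are pairwise-complete, clustering uses an overlap-scaled
distance, and PCA uses NIPALS.

**QC.** Cells are kept when detected genes and total counts lie inside
inclusive bounds (defaults 500–10,000 genes, 1,000–60,000 counts) and the
mitochondrial read fraction is strictly below 0.10 (gene/count bounds
inclusive, mito bound strict, matching how such ranges are conventionally
written). Patients contributing fewer than `min_cells_focal_type` cells of
the focal (tumor) type are excluded; the default of 100 is a configurable
convention — workflows of this kind drop samples with a handful of tumor
cells (single digits to a few dozen) without a canonical cutoff.

**Normalization.** value = ln(1 + count · 10⁴ / cell_total), the standard
single-cell library-size log-normalization; natural logarithm throughout,
so reported log2 fold changes are coefficient / ln 2.

**Variable genes.** Full-scale workflows delegate feature selection to
an external integration routine, so a documented deterministic surrogate
is used: per-gene variance z-scored within 20 equal-occupancy mean bins
(bins are guaranteed ≥ 2 genes; within a degenerate bin the unscaled
variance difference ranks), ties broken by gene id.

**Integration stand-in.** `center_by_batch` subtracts, per gene and
patient, the patient mean over nonzero entries. It exists to exercise the
integrated-data code path and file formats, not to emulate what anchor
based integration preserves: removing each patient's per-gene mean also
removes any group difference, so every quantitative analysis here runs on
the non-integrated (normalized + masked) path, which the pipeline exposes
as a first-class variant. A real integrated matrix can be supplied in its
place.

**Pseudobulk.** value(ct, g, p) = mean over *observed* cells; an entry
exists only when ≥ `min_cells` (default 10) observed cells support it.
With imputed entries masked, averaging over all cells would conflate
missingness with zero expression, so "expressed in at least 10 cells" is
read as a support condition on observed cells, evaluated on the
raw-derived mask (the more conservative reading). Simulated bulk sums
per-cell-type averages with missing → 0 (a patient lacking a cell type
contributes nothing), and its per-gene group log2 ratio uses an ε = 1e-9
pseudocount, an arbitrary but documented regularization.

## Differential expression

Per cell type, genes with observed entries in ≥ `min_patients_per_group`
patients of **both** groups (4 by default, 3 for reduced cohorts) are
tested by per-gene OLS of the pseudobulk values on
[intercept, group, covariates…] over that gene's own complete patients
(per-gene row deletion matches the per-gene eligibility rule). With
residual variance s²_g on d_g degrees of freedom, the empirical-Bayes
prior s²_g ~ s0²·F(d_g, d0) is fitted by the digamma/trigamma moment
method on log s²_g (Newton inversion of the trigamma, tolerance 1e-8,
≤ 100 iterations; d0 above 1e6 is reported infinite, with complete
shrinkage handled by the normal limit). The moderated statistic is

  t̃_g = β_g / sqrt(s̃²_g v_g),  s̃²_g = (d0 s0² + d_g s²_g)/(d0 + d_g),

on d0 + d_g degrees of freedom, v_g the design-based unscaled coefficient
variance. The implementation reproduces the reference Bioconductor
implementation of this statistic to machine precision on a frozen fixture
(see tests). No trend or robust variants and no precision weights are
used: models are fitted directly on the aggregated log values.
BH FDR is applied within cell type; significant counts are
reported at cutoffs 0.05 / 0.1 / 0.2, split by sign(log2FC) with zero
counted as neither. Signatures are the top 50 genes by unadjusted p,
ties broken by |t̃| descending then gene id.

## Correlation homogeneity

Pairwise Pearson correlations between patients' pseudobulk profiles are
computed pairwise-complete with a 10-shared-gene minimum; pairs are
classed A-A / B-B / A-B. At single-cell resolution, each unordered sample
pair is summarized by the mean correlation of 100 cross-sample cell pairs
drawn uniformly **with replacement** (one cell from each sample;
within-sample pairs cannot inform between-sample similarity; the
with/without-replacement choice is a documented convention, with draws
failing the 10-shared-gene minimum redrawn a bounded number of times).
Class differences are tested two ways: Welch t-tests between class r
distributions (unequal variances are the safe default for unpaired t-tests on
correlation distributions), and the random-intercept model
r ~ pair_class + (1 | patient_pair), REML-fitted by profiling the
variance ratio σ²_u/σ²_e on a log grid (33 points in [e⁻¹⁰, e⁶]) with
bounded scalar refinement (xatol 1e-10) and an explicit boundary check at
σ²_u = 0. Pair levels are shared across cell types when records are fitted
jointly; per-cell-type and joint modes are both available. Contrasts between class means
use the normal approximation (a deliberate simplification of
Satterthwaite-type degrees of freedom) and BH across all performed tests.

## Clustering and bootstrap support

Patients are clustered on signature matrices (columns = (cell type, gene)
pairs; union and single-type modes) by complete linkage on the
pairwise-complete scaled Euclidean distance
d(i,j) = sqrt(D/|S_ij| · Σ_{g∈S_ij}(x_ig − x_jg)²); the scaling keeps
distances comparable across pairs with different observed overlap (a documented convention; there is no canonical missing-data rule for
hierarchical clustering). The
agglomeration is a direct O(n³) implementation with ties broken toward
the smaller node-id pair; patient counts are small, and the directness
buys exact, auditable tie behavior. Two-group separation cuts the root
(the last merge), reports an exact-partition flag and the adjusted Rand
index.

Cluster support uses multiscale bootstrap: columns (genes) are resampled
with replacement to round(r·D) columns at scales r = 0.5…1.4 (step 0.1),
each replicate reclustered, and a node counted when its exact
leaf-membership set reappears. With BP_r clamped to [1/(B+1), B/(B+1)],
z_r = Φ⁻¹(1 − BP_r) is fitted against v√r + c/√r by weighted least
squares with weights B·φ(z_r)²/(BP_r(1−BP_r)), and AU = 100·(1−Φ(v−c)).
Flat boundary curves (BP ≡ 0 or ≡ 1 at every scale) admit no probit fit
and are reported directly as AU = 0/100 and flagged. This is the
package's own multiscale procedure, documented here rather than claimed
to replicate any external implementation's internals; AU ≥ BP does not
hold in general.

## NIPALS PCA

Sequential NIPALS with missing entries skipped in every score/loading
update and in the deflation; columns are mean-centered over observed
values and must each have ≥ 1 observation. Defaults: 10 components,
tolerance 1e-8 on the relative score change, 500 iterations; a component
hitting the iteration cap is flagged but the decomposition continues
(accuracy is typically far beyond the flag threshold). Sign convention:
first nonzero loading positive. On complete data the scores match
singular-value PCA.

## Ranked-list enrichment

For a gene list ranked by unadjusted DE p-value (sign ignored), each set
is scored by the minimum hypergeometric upper tail over ranking prefixes
against a user-stated background. Only prefixes ending where a member
enters (plus the full list) are evaluated: at fixed overlap the tail
probability only grows with the prefix length, so the reduced grid loses
no minima (asserted against the all-prefix scan in tests). Because the
minimum over prefixes is not a p-value, family-wise significance is
calibrated by permutation: the ranking is shuffled n_perm times, the
minimum min-p across all sets recorded per shuffle (max-T), and adjusted
p = (r+1)/(n+1). The web service's proprietary multiple-testing
correction is thus replaced by a transparent permutation scheme; the raw
min-p is always reported so any correction can be applied downstream.
Sets smaller than 3 or larger than half the background are skipped. When
a ranking comes from outside the pipeline the background must be given
explicitly — there is no silent default.

## Synthetic cohort generator

The generator emulates the target study design at desk scale: 6 vs 6
patients (full-scale cohorts of this kind run ~15 vs ~10), 5 cell types
("tumor", "stromal", "Tcell", "myeloid", "Bcell") with Poisson(60) cells
per patient (~300 cells/patient, against ~4,000 at full scale), 2,000
genes, and a realized zero fraction calibrated to 0.88 — the sparsity
level at which a median single-nucleus entry is imputed rather than
measured in such cohorts.

Counts are negative binomial (variance μ + μ²/θ, θ = 2 by default) with
log-mean = per-gene baseline (normal, mean ln 0.5, SD 1.5, shared across
cell types up to a SD-0.3 per-(gene, cell type) offset) + patient
deviation + group effect (group B only) + log library factor
(log-normal, SD 0.3). Entry-wise Bernoulli thinning with the single rate
d = (target − z₀)/(1 − z₀), the exact one-step solution of the
calibration equation given the realized pre-thinning zero fraction z₀,
brings the zero fraction to the 0.88 target; a per-gene rate cannot reach
a global target once some genes already exceed it. 5% of genes are
flagged mitochondrial.

**Patient deviation structure.** Each patient deviates from the cohort
mean in three layers, all with group-dependent SD (sd_A = 0.1 <
sd_B = 0.25 by default): a gene-shared scalar per cell type (largely
absorbed by library normalization — it models global capture/size
effects), a rank-4 factor term against fixed gene loadings (scores
N(0, sd), loadings N(0, 1/√4)), and gene-specific jitter at half the SD.
The low-rank layer is essential, not decorative: if patient noise were
independent per gene, selecting the top 50 genes by p-value would stack
chance per-gene group gaps into a spurious multivariate group axis, and
even cell types with no planted effects would separate the groups in
clustering — the opposite of how real cohorts behave, where patient
deviations concentrate on a few shared expression programs. The SDs were
chosen, once, so that the generator's intended properties hold jointly:
group A profile pairs correlate higher than group B pairs (the planted
homogeneity contrast), the union signature separates the groups, the
no-effect tumor signature does not, planted effects are recoverable with
FDR control, and the null moderated-t is calibrated. These properties are
in tension through the same parameters (stronger group-B dispersion aids
the correlation contrast but eventually creates dispersion-driven
cluster separability even under the null), and 0.25 sits in the window
where all hold.

**Planted truth.** The default template plants effects only in "stromal"
and "Tcell": 10% of genes each at |log2 fold change| = 1, 70% negative in
group B, drawn from the better-expressed half of the baseline
distribution — an effect planted on a gene the sparsity leaves
unquantifiable would be truth in name only. The tumor type never carries
effects, encoding the headline contrast (microenvironment differs, tumor
cells do not) as recoverable ground truth.

**What the generator does not emulate.** No biological gene modules or
co-regulation beyond the statistical factor structure, no trajectories,
no doublets or ambient RNA, no batch chemistry, and the dispersion/
variance parameters are free choices, not estimates of any real dataset.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it targets under NB sparsity and hierarchical
patient effects — not performance on any particular real cohort.

## Desk-scale run configuration

`desk_scale_run_config()` pairs the template with proportionate QC bounds
(50–2,000 genes, 100–100,000 counts, mito < 0.10, ≥ 20 focal cells,
n_hvg = 1,500) — the full-scale bounds assume ~20,000-gene nuclei and
would discard every simulated cell — plus n_boot = 500 and n_perm = 500.
Analyses in the tests and the acceptance script run the template at these
sizes: 20 seeds for recovery rates in the test suite, 12 in the
acceptance script, 400–1,000 bootstrap/permutation replicates; sizes
chosen so a complete run finishes in about a minute per seed on one CPU
while leaving the recovery rates stable.

## Sensitivity definition

Sensitivity is reported over planted genes that pass the eligibility
rule. At 88% sparsity a fixed fraction of planted genes falls below the
≥ 4-patients support rule by construction; no method can discover an
untested gene, and including them would measure the sparsity, not the
test.

## Known limitations

- The integration stand-in destroys group signal by construction (above);
  integrated-path results are plumbing-level only.
- LMM contrast p-values use the normal approximation; with few pair
  levels they are anti-conservative relative to Satterthwaite-type
  corrections.
- AU values extrapolate a two-parameter fit over ten scales; for nodes
  with BP near the boundary at every scale they are reported from the
  boundary rule rather than the fit.
- The enrichment calibration is family-wise within one ranked list; it
  does not correct across cell types.
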