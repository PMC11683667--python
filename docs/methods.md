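# Methods

`gliosig` implements a complete analysis chain for glioma-style expression
cohorts: malignant-cell annotation in single-cell data, derivation of a
Cd83⁺ tumor-cell gene signature from a gain-of-function (GOF) versus
wild-type (WT) comparison, gene-set scoring of cells, pseudobulk and bulk
samples, iterative signature refinement, and survival stratification. This
note records the models, their assumptions, the defaults that matter, and
what the synthetic cohorts do and do not establish.

## Malignant-cell annotation (human-style cohorts)

A cell is called malignant if it satisfies **at least one** of three
independent evidence channels.

**Marker mixture classifier.** For each marker gene (SOX2, EGFR, PDGFRA) a
two-component Gaussian mixture is fitted to the log-normalised expression of
all cells by expectation–maximisation. The two classes represent
normal-range and tumor-range expression. EM details: k-means++-style
initialisation on the 1-D values with two seeded restarts, convergence at
|Δ log-likelihood| < 1e-8, at most 500 iterations, and a variance floor of
1e-6 (variance collapse is floored, never an error; all-identical input is a
degeneracy error). Components are sorted by mean; the tumor component is the
one nearer the mean of a labelled tumor reference when one is supplied,
otherwise the higher-mean component. A cell's marker indicator is 1 when
its posterior probability of the tumor component strictly exceeds τ = 0.5
(configurable). With equal weights and variances this posterior is a
logistic function of the expression value, which gives the closed-form
check used in the tests.

The pooled fit assumes marker expression is genuinely bimodal across the
cohort. Strong zero-inflation (a marker detected in almost no normal cells)
degrades the two-component fit, because the zero spike captures one
component and everything detected lands in the other; in that regime a
fixed detection threshold (the mouse-style rule below) is more appropriate.

**Copy-number evidence.** Expression of each gene is centred by its mean
over a user-chosen reference (non-malignant) cell set; genes are ordered
along each chromosome arm (the order of the gene→arm table), smoothed with
a coverage-normalised moving average (window 21 genes; the normalisation
avoids the zero-padding bias that would otherwise shrink arm ends), and
averaged into one score per arm per cell. An arm is called altered when
|score| exceeds 3 standard deviations of the reference cells' scores for
that arm; any altered arm sets the cell's CNV flag. Arms with fewer than 10
mapped genes are skipped with a warning. This is an arm-level simplification
of expression-based CNV callers — it detects broad gains/losses, not focal
or subclonal events — and the pipeline accepts precomputed per-cell flags
from an external caller in its place. Reference cells should be drawn from
across samples; a reference confined to one sample miscalibrates the null
spread of arm scores.

**Variant evidence.** The per-cell variant table is filtered to records
that are COSMIC-documented, have a dbSNP population frequency below 0.1%
(missing frequency counts as unobserved and passes), and match the driver
rules: IDH1/IDH2 restricted to protein changes R132H/R132C, EGFR any
qualifying record. Any passing record flags the cell.

**Mouse-style cohorts** use fixed thresholds on log-normalised marker
expression — Pdgfra > 2.64, Egfr > 2.04, Sox2 > 1.95, strict inequalities —
or GFP count > 0 (lineage label of electroporated tumors). The thresholds
correspond to the 99% quantile of a healthy-brain reference; the package
recomputes such thresholds from any reference with the linear-interpolation
quantile definition.

## QC and normalisation

Genes are kept when detected in more than 3 cells; cells when they express
more than 300 genes, their detected-gene count lies in [200, 5000], and
their mitochondrial count share is below 10% (human) or 20% (mouse). The
two cell criteria (>300 and the 200–5000 window) overlap; both are applied
conjunctively, and "gene count" is read as detected genes, not UMIs. The
gene filter runs first, then the cell filters on the gene-filtered matrix;
the filter is idempotent and never reorders labels.

Single-cell normalisation scales each cell to 10,000 counts and applies
log1p. Bulk normalisation uses median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts, library-size fallback with a
warning) followed by log2(x+1); a full dispersion-trend variance-stabilising
transform is deliberately out of scope — downstream ssGSEA is rank-based,
which limits sensitivity to this choice.

## Signature derivation

Group A is Cd83⁺ (raw count > 0) / Cd45⁻ (raw PTPRC count = 0) tumor cells
from the GOF condition; group B is Cd83⁻/Cd45⁻ tumor cells from WT.
Positivity is a detection statement, so it is defined on raw counts, not
normalised values. Differential expression uses the Wilcoxon rank-sum test
per gene (mid-ranks for ties; exact null by the counting recurrence —
equivalent to full enumeration — when the smaller group has ≤ 8 values and
no ties, otherwise the tie-corrected normal approximation with continuity
correction) and Bonferroni correction over all genes tested. Log fold
changes are log2 ratios of de-logged (expm1) group means with a 1e-9
pseudocount. The signature is the strictly up-regulated set: logFC > 1 and
adjusted p < 0.05, both strict. Mouse symbols map to human by an explicit
ortholog table when given, otherwise by the uppercase heuristic; duplicates
collapse, order is preserved, and the unmapped fraction is reported.

## Scoring

**Module score** (single cells): genes are ranked by mean expression and
cut into 24 equal-frequency bins; each set gene draws 100 control genes
from its own bin (seeded; with replacement when the bin is smaller). The
score is mean set-gene expression minus mean control expression per cell.
Adding a constant to one cell's expression vector leaves its scores
unchanged (set and control means shift equally).

**ssGSEA** (one observation): genes are ranked descending by value, ties
broken by value then gene symbol for determinism. The in-set cumulative
distribution weights the gene at position i by ((N−i)/N)^α (α = 0.25
default; uniform at α = 0, where the score depends on ranks only), the
out-of-set cumulative is uniform, and the score is the sum over ranks of
their difference. No cross-cohort min–max normalisation is applied by
default: scores are compared within one cohort.

**Pseudobulk** sums raw counts over a cell mask (typically tumor calls)
within each sample; empty samples are dropped with a warning.

**Iterative refinement**: each pass scores every sample with ssGSEA on the
current set, computes each retained gene's Pearson correlation with the
score vector across samples, and removes genes with r < 0.5. The loop stops
at a fixed point, when a removal would shrink the set below 10 genes (the
current set is kept), or after 20 passes. Scores are recomputed every pass —
that recomputation is what makes the loop iterative; a single-pass variant
is max_iter = 1. The floor and cap are artifact guarantees of termination
and non-degeneracy, both configurable.

## Cohort statistics

Pearson correlations use the product-moment formula with the two-sided t
test on n−2 degrees of freedom; per-sample panels report unadjusted p
(mirroring panel conventions) plus a Benjamini–Hochberg column. Samples are
stratified at the score quartiles — high: ≥ Q3, low: ≤ Q1, linear
interpolation quantiles, boundary ties included in the extreme groups,
middle half excluded; an all-equal score vector stratifies nobody rather
than everybody. Survival uses the Kaplan–Meier product-limit estimator
(median = first time S(t) ≤ 0.5, undefined when never reached) and the
log-rank test with the exact hypergeometric variance for two groups
(chi-square, 1 df; a k-group extension with k−1 df is available).

## Synthetic cohorts: what they emulate

Counts are negative-binomial with a log-link (dispersion 0.5; variance
mean + 0.5·mean², clearly super-Poisson). Per-gene baselines are log-normal
around log-mean 1.0 (≈5,000-count libraries, so single stray counts land low
after normalisation); cells carry a log-normal library factor (sd 0.3) and
every gene wobbles between samples (sd 0.15 human / 0.05 mouse — human
cohorts are heterogeneous patients, the mouse pair is a controlled
manipulation on inbred littermates).

Default cohort: 4 samples × 500 cells, 50% tumor / 25% immune / 25% normal,
1,200 genes. Markers are elevated three log units in tumor cells, from a
moderate normal baseline in human mode (log-mean 1→4; reactive glia express
these markers) and from a progenitor-restricted baseline in mouse mode
(0→3, which puts the normal 99% quantile near the printed mouse
thresholds). Tumor cells carry +1 log2 on arm 7p and −1 log2 on 10q of an
eight-arm panel (1p/1q/7p/7q/10p/10q/19p/19q, 120 genes each — the
glioma-diagnostic chromosomes). An IDH1 R132H record is captured in 20% of
tumor cells; common-SNP and non-COSMIC decoy records exercise the filters.
Immune cells always have PTPRC > 0; GFP is present only in tumor cells
(mouse mode, 90% capture). Ten mitochondrial genes make up ~5% of counts
(25% in a 4% "stressed" subpopulation, which QC removes).

The Cd83 program is 40 genes (Cd83 itself plus 39 co-induced genes) raised
four-fold (log2FC 2) in GOF tumor cells, Cd83 itself eight-fold (log2FC 3).
Program and immune-module genes sit one log unit below the global baseline
so their library share stays modest — large shares would induce
library-composition artifacts that masquerade as negative correlations in
uncoupled sets. A latent per-sample factor couples module expression to the
program: each immune module has a sign and magnitude (defaults span strong
negative "immunosuppressive" to moderate positive "antitumor" couplings,
plus one uncoupled null module); couplings are scaled 1.0 in human mode and
0.25 in mouse mode.

The bulk generator drives 30 coherent genes with a latent program activity
(0.8 log units per SD) and plants 10 uncorrelated decoys — the mouse-derived
signature genes that fail to transfer across species. Survival times are
exponential with hazard h₀·exp(β·z) for the standardised program score
(h₀ = 0.01/day, β = −log 2 per SD — protective, hazard halves per SD),
censored uniformly on (0, 300] days.

Not emulated: ambient RNA, doublets, batch effects (integration is out of
scope), focal or subclonal CNVs, realistic gene-length or GC structure, and
correlated gene-gene noise within modules beyond the single latent factor.
Passing recovery tests on these cohorts therefore shows the machinery is
correct and calibrated under the stated generative assumptions, not that it
is robust to every artifact of real tissue data.

## Numerical and design notes

- Per-sample correlation panels need enough samples to be informative; the
  demo pipeline's 4-sample mouse cohort reports them with honest p-values
  near 1, while the acceptance run uses a 50-sample human-style cohort where
  planted couplings are recovered with |r| > 0.5 and the correct sign.
- The acceptance script measures Cd83 induction GOF-tumor versus WT-tumor
  (unselected). Within the DE populations themselves group B is selected to
  have zero Cd83 counts, so Cd83's own fold change there is
  pseudocount-dominated and not comparable.
- Exact Wilcoxon enumeration is limited to n₁·n₂ ≤ 2500 (beyond the exact
  regime the tie-corrected normal approximation is used regardless).
- The permutation type-I control for the signature permutes the group-A/B
  assignment within the selected populations. Permuting raw condition
  labels instead would leave the Cd83-positivity selection intact and
  re-select mostly program-carrying cells — a residual true signal, not a
  null.
- Problem sizes in tests and the acceptance script (2,000-cell annotation
  cohorts, 2,800-cell signature cohorts, 50-sample panels, 2,000-replicate
  null calibrations) were chosen so each check is decisive at desk scale;
  all generators are bit-reproducible given (spec, seed), and one global
  seed derives per-stage substreams.

## Known limitations

The classifier assumes the marker's bimodality and the CNV reference are
trustworthy; both degrade gracefully (configurable τ, injectable external
CNV flags) but are not self-diagnosing. Wilcoxon DE on cells ignores
within-sample correlation (pseudoreplication), as is conventional in
single-cell pipelines; with few samples and strong between-sample noise
this inflates false positives, which is visible in the generator if
between-sample noise is raised. The ssGSEA dialect is the integrated
running-sum difference; other dialects (max-deviation statistics,
cross-sample normalisation) give different absolute scores, though
rank-based downstream use limits the impact.
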