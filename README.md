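# gliosig

Malignant-cell calling and immune gene-signature analysis for glioma-style
expression cohorts.

Glioma tissue is a mixture of tumor cells, infiltrating immune cells and
normal brain. Two questions recur in studies of tumor–immune communication:
*which cells in a single-cell experiment are actually malignant*, and *does a
tumor-cell transcriptional program (here, the Cd83⁺ "antigen-presenting-like"
program) track immune composition and patient survival*? `gliosig`
implements that full analysis chain as a tested, reusable library and
command-line pipeline, together with synthetic-cohort generators that make
every stage verifiable without access to patient data.

## What it computes

- **Tumor-cell annotation (human-style data).** A cell is called malignant
  when it meets at least one of three criteria: (i) a per-marker
  two-component Gaussian mixture (fitted by EM on log-normalised SOX2 /
  EGFR / PDGFRA expression) assigns it to the high "tumor" class with
  posterior > τ; (ii) arm-level copy-number evidence — reference-centred,
  positionally smoothed expression — shows a shift beyond 3 reference SDs
  on any chromosome arm; (iii) it carries a rare (dbSNP frequency < 0.1%)
  COSMIC-documented driver variant (IDH1/IDH2 R132H/R132C, or EGFR).
- **Tumor-cell annotation (mouse-style data).** Fixed reference-quantile
  thresholds (Pdgfra > 2.64, Egfr > 2.04, Sox2 > 1.95) or GFP lineage
  labelling.
- **Cd83⁺ signature derivation.** Wilcoxon rank-sum DE between Cd83⁺/Cd45⁻
  tumor cells (gain-of-function condition) and Cd83⁻/Cd45⁻ tumor cells
  (wild-type), thresholded at log2FC > 1 and Bonferroni-adjusted p < 0.05,
  then mapped from mouse to human symbols.
- **Scoring.** Binned-control module scores per cell; ssGSEA (rank-based
  running-sum, weight exponent α = 0.25) per sample; pseudobulk aggregation
  of tumor-cell counts; Pearson correlation panels against immune gene-set
  collections.
- **Iterative refinement.** Repeatedly drop signature genes whose
  expression correlates below r = 0.5 with the current ssGSEA score across
  samples, re-scoring each pass until a fixed point.
- **Survival.** Quartile stratification of sample scores (high ≥ Q3,
  low ≤ Q1), Kaplan–Meier product-limit curves and the log-rank test.

The statistical machinery (EM mixture, exact/approximate Wilcoxon, ssGSEA,
KM, log-rank, binned-control scores) is implemented in-package and checked
against independent oracles — enumeration, brute-force running sums,
permutation nulls, and `sklearn` / `lifelines` cross-checks — in the test
suite.

## Worked example

The pipeline runs end-to-end on a simulated cohort (no external data
needed). One seed controls everything; stages exchange plain files
(Matrix-Market counts, GMT gene sets, TSV tables) so any stage can be
replaced by an external tool's output:

```sh
gliosig --seed 7 --outdir demo --species mouse run-all
```

This simulates a 4-sample, 2,000-cell GOF/WT mouse cohort plus a 60-sample
bulk cohort, applies QC (here 77 of 2,000 cells fail the mitochondrial
filter), annotates tumor cells, derives the signature, scores, refines and
stratifies. It prints per-stage progress and finishes in a few seconds:

```
INFO gliosig.pipeline: stage simulate done in 0.77s
INFO gliosig.pipeline: stage qc done in 1.11s
INFO gliosig.pipeline: stage annotate done in 0.41s
INFO gliosig.pipeline: stage signature done in 0.56s
...
pipeline complete: 8 stages -> demo/manifest.json
```

Key outputs of that run:

- `cd83_signature.gmt` — the derived signature: 40 genes, exactly the
  planted Cd83 program (CD83, PRG1, PRG2, …) after mouse→human mapping.
- `cd83_signature_refined.gmt` — 30 genes after iterative refinement on the
  bulk cohort: the 10 planted non-transferring decoy genes are removed.
- `survival_summary.json` — high-score vs low-score strata:

  ```json
  {
    "chi_square": 18.82,
    "medians": { "high": null, "low": 23.3 },
    "p": 1.44e-05
  }
  ```

  The low-signature stratum has a median survival of 23.3 days while the
  high-signature stratum never drops below 50% survival (`null` median) —
  the planted protective effect (hazard halves per SD of program score),
  recovered by the log-rank test at p ≈ 1.4e-5.
- `correlations.tsv` — the per-sample immune-panel correlations. With only
  4 samples these are honestly uninformative (p ≈ 0.3–0.9); the panel
  becomes decisive at realistic cohort sizes (see the acceptance run, which
  recovers every planted coupling's sign at |r| > 0.5 over 50 samples).

Every stage is also callable as a library function
(`gliosig.annotate.fit_em_gmm`, `gliosig.scoring.iterative_ssgsea`, …); see
`docs/methods.md` for the models, defaults and assumptions.

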