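"""Synthetic cohorts with the statistical structure the pipeline assumes.

The single-cell generator emulates a mixed tumor / immune / normal brain-tumor
cohort: negative-binomial counts with a log-link, elevated tumor-marker
expression in tumor cells, arm-level copy-number shifts, rare driver variants,
mitochondrial-count fractions, an induced Cd83 program in gain-of-function
(GOF) tumor cells, and immune gene modules whose sample-level expression is
coupled (positively or negatively) to the program through a shared latent
sample factor.  A companion bulk generator produces sample-level cohorts with
the same latent-factor structure plus survival times whose hazard depends on
the program score.

Every generator is bit-reproducible given its spec and seed, and every truth
table is sufficient to score downstream calls without re-simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import RAW_COUNTS, ExpressionMatrix, GeneSet, GeneSetCollection

LN2 = math.log(2.0)

#: (name, sign, coupling magnitude) of the planted immune-like modules.  The
#: magnitudes span the strong negative / moderate positive range typical of
#: immunosuppressive vs antitumor modules in glioma cohorts; one uncoupled
#: module is included as a null control.
DEFAULT_IMMUNE_SETS: tuple[tuple[str, int, float], ...] = (
    ("treg_signature", -1, 0.8),
    ("tam_signature", -1, 0.9),
    ("pd1_pdl1_signature", -1, 0.8),
    ("cd8_t_signature", +1, 0.7),
    ("central_memory_t_signature", +1, 0.6),
    ("th_signature", +1, 0.5),
    ("null_signature", +1, 0.0),
)


@dataclass
class MarkerParams:
    """Log-scale negative-binomial mean of a marker in normal vs tumor cells.

    Markers like SOX2/EGFR/PDGFRA are expressed at moderate levels in healthy
    brain and strongly elevated in tumor cells; the defaults encode a
    three-log-unit elevation over a clearly detected baseline.
    """

    normal_mean: float = 1.0
    tumor_mean: float = 4.0
    sd: float = 0.4

    def validate(self) -> None:
        if self.sd <= 0:
            raise ParameterError("marker sd must be > 0")


@dataclass
class SimCohortSpec:
    """Study conditions for the simulated single-cell cohort.

    Defaults describe a small mouse-style cohort: four samples of 500 cells
    (two GOF, two wild-type), half the cells malignant, a quarter immune,
    three tumor markers separated by three log units, two arm-level CNVs of
    one log2 unit each, a rare IDH1 R132H driver captured in 20% of tumor
    cells, and a 40-gene Cd83 program induced four-fold in GOF tumor cells
    (Cd83 itself eight-fold).
    """

    n_samples: int = 4
    cells_per_sample: int = 500
    fraction_tumor: float = 0.5
    fraction_immune: float = 0.25
    n_genes: int = 1200
    species: str = "mouse"
    #: None resolves to species-appropriate defaults: adult mouse brain
    #: restricts these markers to rare progenitors (low baseline), human
    #: glioma cohorts contain reactive glia with broader expression.
    marker_params: dict[str, MarkerParams] | None = None
    cnv_arms: list[tuple[str, float]] = field(default_factory=lambda: [("7p", 1.0), ("10q", -1.0)])
    arm_panel: tuple[str, ...] = ("1p", "1q", "7p", "7q", "10p", "10q", "19p", "19q")
    arm_size: int = 120
    snv_capture_rate: float = 0.2
    benign_variant_rate: float = 0.05
    dispersion: float = 0.5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    library_log_sd: float = 0.3
    #: between-sample biological variability per gene (log scale); real
    #: cohorts never have identical per-gene means across patients.  None
    #: resolves per species: 0.15 for heterogeneous human cohorts, 0.05 for
    #: inbred, protocol-matched mouse littermates.
    sample_gene_log_sd: float | None = None
    n_mito_genes: int = 10
    mito_fraction_normal: float = 0.05
    mito_fraction_stressed: float = 0.25
    fraction_stressed: float = 0.04
    n_program_genes: int = 40
    #: immune/program genes sit one log unit below the global baseline —
    #: a modest share of tumor-cell libraries, as immune-related transcripts
    #: are in real tumors — which keeps library-composition artifacts small
    module_baseline_log_mean: float = -0.5
    program_effect: float = math.log(4.0)  # log2FC 2 in GOF tumor cells
    cd83_effect: float = math.log(8.0)  # log2FC 3 for Cd83 itself
    program_sample_coupling: float = 0.6
    #: scales every latent-factor coupling; None resolves per species (1.0 for
    #: human cohorts, whose program variation is natural between-patient
    #: heterogeneity; 0.25 for the controlled GOF/WT mouse comparison)
    latent_coupling_scale: float | None = None
    immune_sets: tuple[tuple[str, int, float], ...] = DEFAULT_IMMUNE_SETS
    immune_set_size: int = 25
    immune_base_coupling: float = 0.9
    ptprc_log_mean: float = 1.5
    gfp_log_mean: float = 1.0
    gfp_capture: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_params is None:
            base = MarkerParams() if self.species != "mouse" else MarkerParams(0.0, 3.0, 0.4)
            self.marker_params = {
                "SOX2": MarkerParams(base.normal_mean, base.tumor_mean, base.sd),
                "EGFR": MarkerParams(base.normal_mean, base.tumor_mean, base.sd),
                "PDGFRA": MarkerParams(base.normal_mean, base.tumor_mean, base.sd),
            }
        if self.latent_coupling_scale is None:
            self.latent_coupling_scale = 1.0 if self.species != "mouse" else 0.25
        if self.sample_gene_log_sd is None:
            self.sample_gene_log_sd = 0.15 if self.species != "mouse" else 0.05

    def validate(self) -> None:
        if not (0 <= self.fraction_tumor <= 1 and 0 <= self.fraction_immune <= 1):
            raise ParameterError("cell-type fractions must lie in [0, 1]")
        if self.fraction_tumor + self.fraction_immune > 1:
            raise ParameterError("cell-type fractions must sum to <= 1")
        if not 0 <= self.snv_capture_rate <= 1:
            raise ParameterError("snv_capture_rate must lie in [0, 1]")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        for m, p in self.marker_params.items():
            p.validate()
        if self.n_samples < 0 or self.cells_per_sample < 0:
            raise ParameterError("cohort sizes must be non-negative")
        if len(self.immune_sets) < 1:
            raise ParameterError("at least one immune set is required")

    # ------------------------------------------------------------------
    # deterministic gene layout shared by the cohort and gene-set builders
    # ------------------------------------------------------------------
    def _case(self, symbol: str) -> str:
        if self.species == "mouse":
            return symbol.capitalize()
        return symbol.upper()

    @property
    def marker_genes(self) -> list[str]:
        return [self._case(m) for m in self.marker_params]

    @property
    def cd45_gene(self) -> str:
        return self._case("PTPRC")

    @property
    def cd83_gene(self) -> str:
        return self._case("CD83")

    @property
    def program_genes(self) -> list[str]:
        # the program includes Cd83 itself plus its co-induced genes
        base = [self._case(f"PRG{i + 1}") for i in range(self.n_program_genes - 1)]
        return [self.cd83_gene] + base

    @property
    def mito_genes(self) -> list[str]:
        prefix = "mt-" if self.species == "mouse" else "MT-"
        return [f"{prefix}{i + 1}" for i in range(self.n_mito_genes)]

    def immune_set_genes(self, name: str) -> list[str]:
        stem = name.removesuffix("_signature").replace("_", "")
        return [self._case(f"{stem}-{i + 1}") for i in range(self.immune_set_size)]

    def gene_layout(self) -> list[str]:
        genes: list[str] = []
        genes += self.marker_genes
        genes += [self.cd45_gene, self.cd83_gene]
        if self.species == "mouse":
            genes.append("GFP")
        genes += self.mito_genes
        genes += [g for g in self.program_genes if g != self.cd83_gene]
        for name, _, _ in self.immune_sets:
            genes += self.immune_set_genes(name)
        n_background = self.n_genes - len(genes)
        if n_background < 0:
            raise ParameterError("n_genes too small for the configured special genes")
        genes += [f"BG{i + 1:04d}" for i in range(n_background)]
        return genes

    def gene_arm_table(self) -> pd.DataFrame:
        """Assign background genes to the arm panel in contiguous blocks.

        The panel covers the glioma-diagnostic chromosomes (1p/19q codeletion,
        chromosome 7 gain, chromosome 10 loss); genes beyond the panel's
        capacity land on pseudo-arm "other" and are never scored.
        """
        genes = self.gene_layout()
        background = [g for g in genes if g.startswith("BG")]
        records = []
        for i, g in enumerate(background):
            block = i // self.arm_size
            arm = self.arm_panel[block] if block < len(self.arm_panel) else "other"
            records.append({"gene": g, "chrom": arm.rstrip("pq"), "arm": arm})
        return pd.DataFrame(records, columns=["gene", "chrom", "arm"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with variance mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(np.clip(mean, 0, None)).astype(float)
    r = 1.0 / dispersion
    p = r / (r + np.clip(mean, 1e-12, None))
    out = rng.negative_binomial(r, p).astype(float)
    out[mean <= 0] = 0.0
    return out


def simulate_sc_cohort(spec: SimCohortSpec):
    """Simulate a single-cell cohort.

    Returns ``(counts, truth, variants, gene_arm_table)`` where ``counts`` is a
    raw ExpressionMatrix, ``truth`` a per-cell DataFrame (sample, cell type,
    condition, program carriage, CNV arms, stress flag) and ``variants`` a
    per-cell variant-call table in the on-disk schema.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_layout()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_cells = spec.n_samples * spec.cells_per_sample

    # --- per-cell truth -------------------------------------------------
    sample_ids = [f"S{j + 1}" for j in range(spec.n_samples)]
    conditions = {s: ("GOF" if j % 2 == 0 else "WT") for j, s in enumerate(sample_ids)}
    cell_rows = []
    for s in sample_ids:
        n = spec.cells_per_sample
        n_tumor = int(round(n * spec.fraction_tumor))
        n_immune = int(round(n * spec.fraction_immune))
        types = ["tumor"] * n_tumor + ["immune"] * n_immune + ["normal"] * (n - n_tumor - n_immune)
        rng.shuffle(types)
        for k, t in enumerate(types):
            cell_rows.append((f"{s}_c{k + 1}", s, t, conditions[s]))
    truth = pd.DataFrame(cell_rows, columns=["cell_id", "sample_id", "cell_type", "condition"])
    truth["carries_program"] = (truth["cell_type"] == "tumor") & (truth["condition"] == "GOF")
    truth["stressed"] = rng.random(n_cells) < spec.fraction_stressed
    is_tumor = (truth["cell_type"] == "tumor").to_numpy()
    is_immune = (truth["cell_type"] == "immune").to_numpy()
    carries = truth["carries_program"].to_numpy()
    truth["arm_alterations"] = np.where(
        is_tumor, ",".join(a for a, _ in spec.cnv_arms), ""
    )

    # --- per-gene baselines ---------------------------------------------
    base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=len(genes))
    # mitochondrial genes scaled so their expected count share hits the target
    module_genes = [g for g in spec.program_genes if g != spec.cd83_gene]
    for name, _, _ in spec.immune_sets:
        module_genes += spec.immune_set_genes(name)
    module_ix = np.array([gene_idx[g] for g in module_genes])
    base[module_ix] += spec.module_baseline_log_mean - spec.baseline_log_mean
    mito_ix = np.array([gene_idx[g] for g in spec.mito_genes])
    nonmito_total = np.exp(np.delete(base, mito_ix)).sum()
    f = spec.mito_fraction_normal
    target = f / (1 - f) * nonmito_total / len(mito_ix)
    base[mito_ix] = np.log(target)
    # markers and lineage genes are fully determined by cell identity
    special = set(spec.marker_genes) | {spec.cd45_gene, spec.cd83_gene}
    if spec.species == "mouse":
        special.add("GFP")

    # --- log-mean matrix -------------------------------------------------
    logmu = np.tile(base[:, None], (1, n_cells))
    lib = rng.normal(0.0, spec.library_log_sd, size=n_cells)
    logmu += lib[None, :]
    # between-sample biological noise: every gene's mean wobbles per sample
    sample_index = truth["sample_id"].map({s: j for j, s in enumerate(sample_ids)}).to_numpy()
    sample_gene = rng.normal(0.0, spec.sample_gene_log_sd, size=(len(genes), spec.n_samples))
    logmu += sample_gene[:, sample_index]

    for name, params in spec.marker_params.items():
        gi = gene_idx[spec._case(name)]
        cell_means = np.where(is_tumor, params.tumor_mean, params.normal_mean)
        logmu[gi, :] = cell_means + rng.normal(0.0, params.sd, size=n_cells) + lib

    # CD45: expressed by immune cells only
    gi = gene_idx[spec.cd45_gene]
    logmu[gi, :] = np.where(is_immune, spec.ptprc_log_mean + lib, -np.inf)

    # Cd83: low baseline everywhere, induced in program-carrying tumor cells
    gi = gene_idx[spec.cd83_gene]
    logmu[gi, :] = -1.5 + lib + np.where(carries, spec.cd83_effect, 0.0)

    if spec.species == "mouse":
        gi = gene_idx["GFP"]
        captured = is_tumor & (rng.random(n_cells) < spec.gfp_capture)
        logmu[gi, :] = np.where(captured, spec.gfp_log_mean + lib, -np.inf)

    # CNV arm shifts in tumor cells
    arm_table = spec.gene_arm_table()
    for arm, log2_shift in spec.cnv_arms:
        arm_genes = arm_table.loc[arm_table["arm"] == arm, "gene"]
        if arm_genes.empty:
            raise ParameterError(f"configured CNV arm {arm!r} maps to no gene in the arm panel")
        ix = np.array([gene_idx[g] for g in arm_genes])
        logmu[np.ix_(ix, np.where(is_tumor)[0])] += log2_shift * LN2

    # Cd83 program induction in GOF tumor cells
    prog_ix = np.array([gene_idx[g] for g in spec.program_genes if g != spec.cd83_gene])
    logmu[np.ix_(prog_ix, np.where(carries)[0])] += spec.program_effect

    # latent sample factor couples immune modules to the program
    u = rng.normal(0.0, 1.0, size=spec.n_samples)
    u_of_cell = truth["sample_id"].map(dict(zip(sample_ids, u))).to_numpy()
    scale = spec.latent_coupling_scale
    all_prog_ix = np.array([gene_idx[g] for g in spec.program_genes])
    logmu[np.ix_(all_prog_ix, np.arange(n_cells))] += (
        scale * spec.program_sample_coupling * u_of_cell[None, :]
    )
    for name, sign, magnitude in spec.immune_sets:
        ix = np.array([gene_idx[g] for g in spec.immune_set_genes(name)])
        logmu[np.ix_(ix, np.arange(n_cells))] += (
            scale * sign * magnitude * spec.immune_base_coupling * u_of_cell[None, :]
        )

    # stressed cells: elevated mitochondrial share
    if spec.mito_fraction_normal > 0:
        boost = math.log(
            (spec.mito_fraction_stressed / (1 - spec.mito_fraction_stressed))
            / (spec.mito_fraction_normal / (1 - spec.mito_fraction_normal))
        )
        stressed = truth["stressed"].to_numpy()
        logmu[np.ix_(mito_ix, np.where(stressed)[0])] += boost

    # --- draw counts -----------------------------------------------------
    with np.errstate(over="ignore"):
        mu = np.exp(logmu)
    counts = _nb_draw(rng, mu, spec.dispersion)
    # immune cells have nonzero CD45 by construction
    gi = gene_idx[spec.cd45_gene]
    counts[gi, is_immune] = np.maximum(counts[gi, is_immune], 1.0)

    expr = ExpressionMatrix(counts, genes, truth["cell_id"].tolist(), mode=RAW_COUNTS)

    # --- variant table ---------------------------------------------------
    records = []
    for cid, tumor in zip(truth["cell_id"], is_tumor):
        if tumor and rng.random() < spec.snv_capture_rate:
            records.append((cid, "IDH1", "var_IDH1_R132H", "R132H", 1, np.nan))
        if rng.random() < spec.benign_variant_rate:
            records.append((cid, "PDGFRB", "var_common_cosmic", "V10I", 1, 0.05))
        if rng.random() < spec.benign_variant_rate:
            records.append((cid, "TTN", "var_rare_noncosmic", "A2T", 0, np.nan))
    variants = pd.DataFrame(
        records, columns=["cell_id", "gene", "variant_id", "protein_change", "in_cosmic", "dbsnp_freq"]
    )
    return expr, truth, variants, arm_table


def simulate_gene_sets(spec: SimCohortSpec) -> GeneSetCollection:
    """Gene-set collection matching the cohort's planted structure.

    Contains the planted Cd83 program set (named ``cd83_program``) followed by
    the immune-like modules; membership is fixed by the spec's deterministic
    gene layout, so the collection is valid for any cohort simulated from the
    same spec.
    """
    spec.validate()
    coll = GeneSetCollection()
    coll.add(GeneSet("cd83_program", list(spec.program_genes), "planted Cd83 tumor program"))
    for name, sign, magnitude in spec.immune_sets:
        coll.add(
            GeneSet(
                name,
                spec.immune_set_genes(name),
                f"planted immune module, coupling {sign * magnitude:+.2f}",
            )
        )
    return coll


@dataclass
class SurvivalParams:
    """Exponential survival with log-hazard linear in the standardized score."""

    baseline_hazard: float = 0.01
    log_hazard_per_sd: float = -math.log(2.0)
    censoring_horizon: float = 300.0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")
        if self.censoring_horizon <= 0:
            raise ParameterError("censoring_horizon must be > 0")


def simulate_survival(sample_scores, params: SurvivalParams, seed: int) -> pd.DataFrame:
    """Per-sample time-to-event table driven by a score.

    ``time = min(T, C)`` with ``T ~ Exp(h0 * exp(beta * z))`` for the
    standardized score ``z`` and ``C ~ Uniform(0, horizon]``; ``event = 1``
    iff failure precedes censoring.
    """
    params.validate()
    scores = pd.Series(sample_scores, dtype=float)
    rng = np.random.default_rng(seed)
    sd = scores.std(ddof=0)
    z = (scores - scores.mean()) / sd if sd > 0 else scores * 0.0
    hazard = params.baseline_hazard * np.exp(params.log_hazard_per_sd * z.to_numpy())
    failure = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0.0, params.censoring_horizon, size=len(scores))
    time = np.minimum(failure, censor)
    event = (failure <= censor).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [str(i) for i in scores.index],
            "time": time,
            "event": event,
        }
    )


def simulate_bulk_cohort(
    n_samples: int = 60,
    n_background: int = 400,
    n_coherent: int = 30,
    n_decoy: int = 10,
    latent_effect: float = 0.8,
    depth_log_sd: float = 0.2,
    dispersion: float = 0.3,
    base_log_mean: float = 3.0,
    base_log_sd: float = 1.0,
    coherent_genes: list[str] | None = None,
    decoy_genes: list[str] | None = None,
    seed: int = 0,
):
    """Bulk-style cohort for refinement and survival stages.

    A latent per-sample program activity drives the coherent genes (log-mean
    shifted by ``latent_effect`` per SD); decoy genes are uncorrelated noise,
    emulating mouse-derived signature genes whose program membership does not
    transfer to the human cohort.  Returns ``(counts, candidate_set,
    latent_scores)`` where ``candidate_set`` is the coherent+decoy gene set a
    mapped signature would score, and ``latent_scores`` the true program
    activity per sample.
    """
    if n_samples < 3:
        raise ParameterError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    coherent = list(coherent_genes) if coherent_genes is not None else [f"PRG{i + 1}" for i in range(n_coherent)]
    decoys = list(decoy_genes) if decoy_genes is not None else [f"DEC{i + 1}" for i in range(n_decoy)]
    n_coherent, n_decoy = len(coherent), len(decoys)
    background = [f"BG{i + 1:04d}" for i in range(n_background)]
    genes = coherent + decoys + background
    u = rng.normal(0.0, 1.0, size=n_samples)
    depth = rng.normal(0.0, depth_log_sd, size=n_samples)
    base = rng.normal(base_log_mean, base_log_sd, size=len(genes))
    logmu = base[:, None] + depth[None, :]
    logmu[: n_coherent, :] += latent_effect * u[None, :]
    mu = np.exp(logmu)
    counts = _nb_draw(rng, mu, dispersion)
    samples = [f"B{i + 1}" for i in range(n_samples)]
    expr = ExpressionMatrix(counts, genes, samples, mode=RAW_COUNTS)
    candidate = GeneSet("cd83_program_mapped", coherent + decoys, "coherent + decoy candidate set")
    scores = pd.Series(u, index=samples)
    return expr, candidate, scores
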