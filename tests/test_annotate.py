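"""Three-evidence malignancy classifier: mixture model, CNV, SNV, OR rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gliosig.annotate import (
    DEFAULT_DRIVER_RULES,
    MarkerMixtureModel,
    annotate_mouse_tumor,
    assign_tumor_component,
    call_tumor_cells,
    cnv_evidence,
    fit_em_gmm,
    marker_indicator_matrix,
    reference_quantile_thresholds,
    snv_evidence,
)
from gliosig.errors import DegenerateDataError, ParameterError
from gliosig.io import LOG_NORMALIZED, ExpressionMatrix
from gliosig.simulate import SimCohortSpec, simulate_sc_cohort


def _mixture_sample(rng, n=5000, w=0.6, mu=(0.0, 3.0), sd=(1.0, 1.0)):
    comp = rng.random(n) < w
    return np.where(comp, rng.normal(mu[0], sd[0], n), rng.normal(mu[1], sd[1], n))


class TestEmGmm:
    def test_parameter_recovery(self):
        x = _mixture_sample(np.random.default_rng(7))
        model = fit_em_gmm(x, seed=1)
        assert abs(model.means[0] - 0.0) < 0.1 and abs(model.means[1] - 3.0) < 0.1
        assert abs(model.weights[0] - 0.6) < 0.03

    def test_posteriors_normalize(self):
        x = _mixture_sample(np.random.default_rng(2), n=500)
        model = fit_em_gmm(x, seed=1)
        resp = model.responsibilities(x)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_loglik_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), size=rng.integers(50, 400))
        model = fit_em_gmm(x, seed=seed)
        trace = np.asarray(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-7)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_em_gmm(np.full(100, 2.5))

    def test_too_few_values(self):
        with pytest.raises(ParameterError):
            fit_em_gmm([1.0, 2.0, 3.0])

    def test_agrees_with_sklearn(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = _mixture_sample(np.random.default_rng(11))
        ours = fit_em_gmm(x, seed=0)
        gm = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        ref_means = np.sort(gm.means_.ravel())
        np.testing.assert_allclose(np.sort(ours.means), ref_means, atol=0.05)


class TestAssignTumorComponent:
    def _model(self):
        return MarkerMixtureModel("SOX2", np.array([0.5, 0.5]), np.array([0.1, 2.9]), np.array([1.0, 1.0]))

    def test_reference_guided(self):
        m = assign_tumor_component(self._model(), [0.0, 3.0, 3.1], ["normal", "tumor", "tumor"])
        assert m.tumor_component == 1

    def test_higher_mean_fallback(self):
        assert assign_tumor_component(self._model()).tumor_component == 1

    def test_adversarial_labels_follow_nearest_mean(self):
        m = assign_tumor_component(self._model(), [0.0, 0.1], ["tumor", "tumor"])
        # one-class labels -> fallback; two-class with tumor mean at 0 -> component 0
        assert m.tumor_component == 1  # fallback (only one class present)
        m2 = assign_tumor_component(self._model(), [0.0, 2.9], ["tumor", "normal"])
        assert m2.tumor_component == 0


class TestMarkerIndicators:
    def _expr(self, values):
        return ExpressionMatrix(
            np.asarray(values, float)[None, :], ["SOX2"], [f"c{i}" for i in range(len(values))], mode=LOG_NORMALIZED
        )

    def _model(self):
        return MarkerMixtureModel("SOX2", np.array([0.5, 0.5]), np.array([0.0, 3.0]), np.array([1.0, 1.0]))

    def test_closed_form_posterior(self):
        # equal weights/variances: posterior is logistic in value, crossing at 1.5
        ind = marker_indicator_matrix({"SOX2": self._model()}, self._expr([3.0, 0.0]))
        assert ind.loc["SOX2"].tolist() == [1, 0]

    def test_boundary_is_strict(self):
        ind = marker_indicator_matrix({"SOX2": self._model()}, self._expr([1.5]))
        assert ind.loc["SOX2"].tolist() == [0]  # posterior exactly 0.5, strict >

    def test_all_zero_column_not_flagged(self):
        ind = marker_indicator_matrix({"SOX2": self._model()}, self._expr([0.0, 0.0]))
        assert ind.to_numpy().sum() == 0

    def test_missing_marker_listed(self):
        expr = ExpressionMatrix(np.zeros((1, 2)), ["EGFR"], ["c0", "c1"], mode=LOG_NORMALIZED)
        with pytest.raises(ParameterError, match="SOX2"):
            marker_indicator_matrix({"SOX2": self._model()}, expr)

    def test_monotone_in_value(self):
        model = self._model()
        values = np.linspace(-2, 6, 200)
        ind = marker_indicator_matrix({"SOX2": model}, self._expr(values)).loc["SOX2"].to_numpy()
        assert np.all(np.diff(ind) >= 0)  # once positive, stays positive


class TestCnvEvidence:
    def test_identical_cells_never_called(self):
        values = np.tile(np.linspace(0, 2, 30)[:, None], (1, 12))
        expr = ExpressionMatrix(values, [f"BG{i:04d}" for i in range(30)], [f"c{i}" for i in range(12)], mode=LOG_NORMALIZED)
        arms = pd.DataFrame({"gene": expr.gene_ids, "chrom": "1", "arm": "1p"})
        flags, scores = cnv_evidence(expr, arms, expr.obs_ids[:6], min_genes_per_arm=10)
        assert not flags.any()

    def test_small_arm_skipped_with_warning(self, human_cohort):
        ln = human_cohort["lognorm"]
        arms = pd.DataFrame({"gene": ln.gene_ids[:3], "chrom": "1", "arm": "1p"})
        flags, scores = cnv_evidence(ln, arms, ln.obs_ids[:50], min_genes_per_arm=10)
        assert scores.shape[1] == 0 and not flags.any()

    def test_recovery_on_planted_shift(self, human_cohort):
        ln, truth, arms = human_cohort["lognorm"], human_cohort["truth"], human_cohort["arms"]
        is_tumor = (truth["cell_type"] == "tumor").to_numpy()
        ref = [c for c, t in zip(ln.obs_ids, is_tumor) if not t][::3][:330]
        flags, _ = cnv_evidence(ln, arms, ref)
        assert flags[is_tumor].mean() >= 0.9
        assert 1 - flags[~is_tumor].mean() >= 0.9

    def test_reference_null_calibration(self):
        # cohort without CNV: self-scored reference alteration rate stays near nominal
        spec = SimCohortSpec(seed=77, species="human", cnv_arms=[], n_samples=2, cells_per_sample=400)
        expr, truth, _, arms = simulate_sc_cohort(spec)
        from gliosig.qc import QCThresholds, apply_qc, lognormalize

        f, _ = apply_qc(expr, QCThresholds.for_species("human"), [g.startswith("MT-") for g in expr.gene_ids])
        ln = lognormalize(f)
        ref = ln.obs_ids[::2]
        flags, scores = cnv_evidence(ln, arms, ref)
        n_arms = scores.shape[1]
        from scipy.stats import norm

        nominal = n_arms * 2 * norm.sf(3.0)
        assert flags[ref].mean() <= 2 * nominal + 0.01


class TestSnvEvidence:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "gene", "variant_id", "protein_change", "in_cosmic", "dbsnp_freq"])

    def test_idh1_r132h_flags_cell(self):
        t = self._table([("c1", "IDH1", "v1", "R132H", 1, 0.0)])
        flags = snv_evidence(t, ["c1", "c2"])
        assert flags["c1"] and not flags["c2"]

    def test_common_variant_fails_rarity(self):
        t = self._table([("c1", "IDH1", "v1", "R132H", 1, 0.05)])
        assert not snv_evidence(t, ["c1"]).any()

    def test_gene_outside_driver_rules_ignored(self):
        t = self._table([("c2", "TP53", "v2", "R175H", 1, np.nan)])
        assert not snv_evidence(t, ["c2"]).any()

    def test_egfr_any_change_and_missing_freq_passes(self):
        t = self._table([("c3", "EGFR", "v3", "A289V", 1, np.nan)])
        assert snv_evidence(t, ["c3"]).all()

    def test_rule_table_enumeration(self):
        cases = []
        for gene in ("IDH1", "IDH2", "EGFR", "TP53"):
            for change in ("R132H", "R132C", "R175H"):
                cases.append((f"{gene}_{change}", gene, "v", change, 1, 0.0))
        flags = snv_evidence(self._table(cases), [c[0] for c in cases])
        for cid, gene, _, change, _, _ in cases:
            rule = DEFAULT_DRIVER_RULES.get(gene, "absent")
            expected = rule is None or (rule != "absent" and change in rule)
            assert flags[cid] == expected


class TestCallRule:
    def test_exhaustive_truth_table(self):
        combos = list(itertools.product([0, 1], repeat=3))
        ind = pd.DataFrame({f"c{i}": [m] for i, (m, _, _) in enumerate(combos)}, index=["SOX2"])
        cnv = pd.Series([c for _, c, _ in combos], index=ind.columns, dtype=bool)
        snv = pd.Series([s for _, _, s in combos], index=ind.columns, dtype=bool)
        calls = call_tumor_cells(ind, cnv, snv)
        for i, combo in enumerate(combos):
            assert calls[f"c{i}"] == any(combo)

    def test_misaligned_inputs_rejected(self):
        ind = pd.DataFrame({"c1": [0]}, index=["SOX2"])
        with pytest.raises(ParameterError):
            call_tumor_cells(ind, pd.Series([False], index=["c2"]), pd.Series([False], index=["c1"]))

    def test_end_to_end_f1_on_default_cohort(self, human_cohort):
        ln, truth = human_cohort["lognorm"], human_cohort["truth"]
        is_tumor = (truth["cell_type"] == "tumor").to_numpy()
        models = {
            m: assign_tumor_component(fit_em_gmm(ln.gene_values(m), marker=m, seed=11))
            for m in ("SOX2", "EGFR", "PDGFRA")
        }
        ind = marker_indicator_matrix(models, ln)
        ref = [c for c, t in zip(ln.obs_ids, is_tumor) if not t][::3][:330]
        cnv, _ = cnv_evidence(ln, human_cohort["arms"], ref)
        snv = snv_evidence(human_cohort["variants"], ln.obs_ids)
        calls = call_tumor_cells(ind, cnv, snv).to_numpy()
        tp = (calls & is_tumor).sum()
        precision = tp / calls.sum()
        recall = tp / is_tumor.sum()
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9


class TestMouseMode:
    def test_reference_quantile_linear_interpolation(self):
        expr = ExpressionMatrix(
            np.arange(1.0, 101.0)[None, :], ["Sox2"], [f"c{i}" for i in range(100)], mode=LOG_NORMALIZED
        )
        thr = reference_quantile_thresholds(expr, ["Sox2"], q=0.99)
        assert thr["Sox2"] == pytest.approx(99.01)
        assert reference_quantile_thresholds(expr, ["Sox2"], q=1.0)["Sox2"] == 100.0

    def test_constant_reference(self):
        expr = ExpressionMatrix(np.full((1, 20), 2.0), ["Sox2"], [f"c{i}" for i in range(20)], mode=LOG_NORMALIZED)
        assert reference_quantile_thresholds(expr, ["Sox2"], q=0.99)["Sox2"] == 2.0

    def _mouse_expr(self, sox2):
        values = np.zeros((3, len(sox2)))
        values[0, :] = sox2
        return ExpressionMatrix(values, ["Sox2", "Egfr", "Pdgfra"], [f"c{i}" for i in range(len(sox2))], mode=LOG_NORMALIZED)

    def test_printed_threshold_behavior(self):
        calls = annotate_mouse_tumor(self._mouse_expr([2.10, 1.95, 1.96]), gfp_counts=[0, 0, 0])
        assert calls.tolist() == [True, False, True]  # strict > at Sox2 = 1.95

    def test_gfp_alone_is_sufficient(self):
        calls = annotate_mouse_tumor(self._mouse_expr([0.0]), gfp_counts=[1])
        assert calls.tolist() == [True]
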