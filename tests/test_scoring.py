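"""Module scores, ssGSEA vs a literal brute-force oracle, pseudobulk, refinement."""

import numpy as np
import pandas as pd
import pytest

from gliosig.errors import ParameterError
from gliosig.io import LOG_NORMALIZED, RAW_COUNTS, ExpressionMatrix, GeneSet, GeneSetCollection
from gliosig.qc import normalize_bulk
from gliosig.scoring import (
    ScoreTable,
    iterative_ssgsea,
    module_score,
    pseudobulk,
    score_panel,
    ssgsea_score,
    ssgsea_scores,
)
from gliosig.simulate import SimCohortSpec, simulate_bulk_cohort, simulate_gene_sets


def brute_force_ssgsea(values, genes, members, alpha):
    """Term-by-term evaluation of the running-sum definition."""
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    n = len(genes)
    in_set = [genes[i] in members for i in order]
    weights = [((n - pos) / n) ** alpha for pos in range(n)]
    denom_in = sum(w for w, m in zip(weights, in_set) if m)
    denom_out = n - sum(in_set)
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for pos in range(n):
        if in_set[pos]:
            cum_in += weights[pos]
        else:
            cum_out += 1.0
        score += cum_in / denom_in - cum_out / denom_out
    return score


class TestSsgsea:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        values = rng.normal(size=20)
        members = set(rng.choice(genes, size=rng.integers(2, 10), replace=False))
        for alpha in (0.0, 0.25, 1.0):
            ours = ssgsea_score(values, genes, GeneSet("s", sorted(members)), alpha=alpha)
            ref = brute_force_ssgsea(values, genes, members, alpha)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_hand_computed_top_two(self):
        # 5 genes, set = top-2 by value, alpha=0: P_in jumps 1/2 at ranks 1,2
        genes = ["a", "b", "c", "d", "e"]
        values = [5.0, 4.0, 3.0, 2.0, 1.0]
        score = ssgsea_score(values, genes, GeneSet("s", ["a", "b"]), alpha=0.0)
        # positions: P_in = .5,1,1,1,1 ; P_out = 0,0,1/3,2/3,1
        expected = (0.5 - 0) + (1 - 0) + (1 - 1 / 3) + (1 - 2 / 3) + (1 - 1)
        assert score == pytest.approx(expected)

    def test_rank_invariance_at_alpha_zero(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = rng.normal(size=30)
        s = GeneSet("s", list(rng.choice(genes, 8, replace=False)))
        base = ssgsea_score(values, genes, s, alpha=0.0)
        for transform in (np.exp, lambda v: v**3, lambda v: 10 * v + 2):
            assert ssgsea_score(transform(values), genes, s, alpha=0.0) == pytest.approx(base, abs=1e-12)

    def test_bottom_ranked_set_scores_negative(self):
        genes = [f"g{i}" for i in range(20)]
        values = np.arange(20.0, 0.0, -1.0)
        s = GeneSet("s", genes[-5:])
        assert ssgsea_score(values, genes, s, alpha=0.0) < 0

    def test_full_coverage_set_rejected(self):
        genes = ["a", "b"]
        with pytest.raises(ParameterError):
            ssgsea_score([1.0, 2.0], genes, GeneSet("s", genes))


class TestModuleScore:
    def _homogeneous(self, rng, n_genes=200, n_cells=50):
        values = rng.normal(2.0, 0.3, size=(n_genes, n_cells))
        return ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)], [f"c{i}" for i in range(n_cells)], mode=LOG_NORMALIZED)

    def test_whole_transcriptome_set_scores_near_zero(self, rng):
        expr = self._homogeneous(rng)
        s = GeneSet("all", expr.gene_ids)
        score = module_score(expr, s, n_bins=10, seed=0)
        assert abs(score.mean()) < 0.05

    def test_deterministic_given_seed(self, rng):
        expr = self._homogeneous(rng)
        s = GeneSet("s", expr.gene_ids[:20])
        a = module_score(expr, s, seed=5, n_bins=10)
        b = module_score(expr, s, seed=5, n_bins=10)
        pd.testing.assert_series_equal(a, b)

    def test_translation_equivariance(self, rng):
        expr = self._homogeneous(rng)
        s = GeneSet("s", expr.gene_ids[:25])
        base = module_score(expr, s, seed=3, n_bins=10)
        shifted_vals = expr.values.copy()
        shifted_vals[:, 0] += 1.7  # shift one cell's whole expression vector
        shifted = ExpressionMatrix(shifted_vals, expr.gene_ids, expr.obs_ids, mode=LOG_NORMALIZED)
        after = module_score(shifted, s, seed=3, n_bins=10)
        assert after.iloc[0] == pytest.approx(base.iloc[0], abs=1e-9)
        pd.testing.assert_series_equal(after.iloc[1:], base.iloc[1:])

    def test_planted_program_separates_carriers(self, mouse_cohort):
        spec = mouse_cohort["spec"]
        sets = simulate_gene_sets(spec)
        score = module_score(mouse_cohort["lognorm"], sets["cd83_program"], seed=0)
        carries = mouse_cohort["truth"]["carries_program"].to_numpy()
        from scipy.stats import rankdata

        ranks = rankdata(score)
        n1, n2 = carries.sum(), (~carries).sum()
        auc = (ranks[carries].sum() - n1 * (n1 + 1) / 2) / (n1 * n2)
        assert auc > 0.9

    def test_no_gene_present_rejected(self, rng):
        expr = self._homogeneous(rng)
        with pytest.raises(ParameterError):
            module_score(expr, GeneSet("s", ["absent1", "absent2"]), n_bins=10)


class TestPseudobulk:
    def test_additivity(self):
        counts = ExpressionMatrix(np.array([[1.0, 3.0], [2.0, 4.0]]), ["g1", "g2"], ["c1", "c2"])
        pb = pseudobulk(counts, pd.Series({"c1": "s1", "c2": "s1"}))
        np.testing.assert_array_equal(pb.values[:, 0], [4.0, 6.0])

    def test_single_cell_identity(self):
        counts = ExpressionMatrix(np.array([[1.0, 3.0], [2.0, 4.0]]), ["g1", "g2"], ["c1", "c2"])
        pb = pseudobulk(counts, pd.Series({"c1": "s1", "c2": "s2"}), [True, False])
        assert pb.obs_ids == ["s1"]
        np.testing.assert_array_equal(pb.values[:, 0], [1.0, 2.0])

    def test_conservation_of_masked_counts(self, rng):
        counts = ExpressionMatrix(
            rng.integers(0, 20, size=(30, 40)).astype(float),
            [f"g{i}" for i in range(30)],
            [f"c{i}" for i in range(40)],
        )
        samples = pd.Series([f"s{i % 4}" for i in range(40)], index=counts.obs_ids)
        mask = rng.random(40) < 0.6
        pb = pseudobulk(counts, samples, mask)
        assert pb.values.sum() == counts.values[:, mask].sum()

    def test_empty_mask_rejected(self):
        counts = ExpressionMatrix(np.ones((2, 2)), ["g1", "g2"], ["c1", "c2"])
        with pytest.raises(ParameterError):
            pseudobulk(counts, pd.Series({"c1": "s1", "c2": "s1"}), [False, False])


class TestIterativeRefinement:
    def test_fixed_point_returns_input_set(self):
        expr, candidate, latent = simulate_bulk_cohort(
            n_samples=60, n_decoy=0, latent_effect=2.0, dispersion=0.05, seed=1
        )
        norm = normalize_bulk(expr)
        coherent_only = GeneSet("s", [g for g in candidate.genes if g.startswith("PRG")])
        refined, scores, trace = iterative_ssgsea(norm, coherent_only)
        assert refined.genes == coherent_only.genes
        assert trace.n_iterations == 1

    def test_decoys_removed_coherent_retained(self):
        for seed in range(3):
            expr, candidate, _ = simulate_bulk_cohort(n_samples=50, seed=seed)
            refined, _, trace = iterative_ssgsea(normalize_bulk(expr), candidate)
            assert not any(g.startswith("DEC") for g in refined.genes)
            retained = sum(g.startswith("PRG") for g in refined.genes)
            assert retained >= 27  # >= 90% of the 30 coherent genes
            assert trace.n_iterations <= 20

    def test_final_set_satisfies_threshold(self):
        expr, candidate, _ = simulate_bulk_cohort(n_samples=50, seed=9)
        norm = normalize_bulk(expr)
        refined, scores, _ = iterative_ssgsea(norm, candidate)
        final = scores.scores.iloc[:, 0]
        pos = {g: i for i, g in enumerate(norm.gene_ids)}
        for g in refined.genes:
            r = np.corrcoef(norm.values[pos[g], :], final.to_numpy())[0, 1]
            assert r >= 0.5

    def test_too_few_present_genes_rejected(self):
        expr, _, _ = simulate_bulk_cohort(n_samples=20, seed=0)
        norm = normalize_bulk(expr)
        with pytest.raises(ParameterError):
            iterative_ssgsea(norm, GeneSet("s", ["PRG1", "PRG2", "ABSENT"]), min_set_size=10)

    def test_min_size_floor_keeps_current_set(self):
        # a set of pure decoys would shrink to nothing; the floor must hold it
        expr, candidate, _ = simulate_bulk_cohort(n_samples=40, seed=4)
        decoys = GeneSet("d", [g for g in candidate.genes if g.startswith("DEC")])
        refined, _, _ = iterative_ssgsea(normalize_bulk(expr), decoys, min_set_size=10)
        assert len(refined.genes) == 10


class TestScorePanel:
    def test_one_column_per_set(self, rng):
        values = rng.normal(2, 0.5, size=(60, 15))
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(60)], [f"c{i}" for i in range(15)], mode=LOG_NORMALIZED)
        coll = GeneSetCollection(
            [GeneSet("s1", expr.gene_ids[:5]), GeneSet("s2", expr.gene_ids[5:10]), GeneSet("s3", expr.gene_ids[10:15])]
        )
        table = score_panel(expr, coll, method="module_score", n_bins=6, seed=0)
        assert list(table.scores.columns) == ["s1", "s2", "s3"]

    def test_absent_set_is_skipped_and_reported(self, rng):
        values = rng.normal(2, 0.5, size=(30, 10))
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(10)], mode=LOG_NORMALIZED)
        coll = GeneSetCollection([GeneSet("ok", expr.gene_ids[:4]), GeneSet("gone", ["x1", "x2"])])
        table = score_panel(expr, coll, method="module_score", n_bins=6, seed=0)
        assert table.skipped == ["gone"]
        assert list(table.scores.columns) == ["ok"]
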