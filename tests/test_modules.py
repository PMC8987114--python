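import numpy as np
import pytest
from scipy import stats

import coexdiff as cd


def tom_dissimilarity(expr, power=5):
    S = cd.correlation_matrix(expr)
    return cd.dist_tom(cd.tom(cd.adjacency(S, power)))


@pytest.fixture(scope="module")
def detected(default_sim):
    expr, traits, truth = default_sim
    dist = tom_dissimilarity(expr)
    dend, assignment = cd.detect_modules(dist, expr.gene_ids)
    me = cd.module_eigengenes(expr, assignment)
    return expr, traits, truth, assignment, me


class TestClusterSamples:
    def test_homogeneous_all_retained(self, default_sim):
        expr, _, _ = default_sim
        _, kept = cd.cluster_samples(expr)
        assert kept == expr.sample_ids

    def test_constructed_outlier_removed(self):
        rng = np.random.default_rng(21)
        values = rng.standard_normal((200, 60))
        values[:, 0] += 10.0  # +10 SD shift on all genes
        expr = cd.ExpressionMatrix(
            tuple(f"G{i}" for i in range(200)),
            tuple(f"S{i}" for i in range(60)), values,
        )
        _, kept = cd.cluster_samples(expr)
        assert "S0" not in kept
        assert len(kept) == 59

    def test_quantile_one_retains_all(self):
        rng = np.random.default_rng(22)
        values = rng.standard_normal((50, 20))
        values[:, 3] += 10.0
        expr = cd.ExpressionMatrix(
            tuple(f"G{i}" for i in range(50)),
            tuple(f"S{i}" for i in range(20)), values,
        )
        _, kept = cd.cluster_samples(expr, cut_height_quantile=1.0)
        assert len(kept) == 20


class TestDetectModules:
    def test_planted_recovery(self, detected):
        _, _, truth, assignment, _ = detected
        assert len(assignment.modules()) == 4
        assert cd.score_module_recovery(assignment, truth) >= 0.9

    def test_grey_mostly_background(self, detected):
        _, _, truth, assignment, _ = detected
        grey = [g for g in assignment.gene_ids if assignment.label_of(g) == "grey"]
        background = [g for g in grey if truth.module_of_gene[g] == 0]
        assert len(background) / len(grey) > 0.8

    def test_min_size_above_all_clusters_gives_grey(self, default_sim, caplog):
        expr, _, _ = default_sim
        dist = tom_dissimilarity(expr)
        with caplog.at_level("WARNING", logger="coexdiff"):
            _, assignment = cd.detect_modules(dist, expr.gene_ids,
                                              min_module_size=200)
        assert assignment.modules() == {}
        assert all(assignment.label_of(g) == "grey" for g in assignment.gene_ids)

    def test_deterministic_repeat(self, default_sim):
        expr, _, _ = default_sim
        dist = tom_dissimilarity(expr)
        _, a1 = cd.detect_modules(dist, expr.gene_ids)
        _, a2 = cd.detect_modules(dist, expr.gene_ids)
        assert a1.assignment == a2.assignment

    def test_equal_size_tie_break_lexicographic(self):
        # two identical-size planted modules: labels must order by the
        # lexicographically smallest member gene id
        params = cd.SimulationParams(
            n_genes=100, module_sizes=(50, 50), rho=0.8,
            trait_linked_modules=(), n_samples=(60, 60), seed=13,
        )
        expr, _, _ = cd.simulate(params)
        dist = tom_dissimilarity(expr)
        _, assignment = cd.detect_modules(dist, expr.gene_ids)
        modules = assignment.modules()
        sizes = {label: len(genes) for label, genes in modules.items()}
        if sizes.get("turquoise") == sizes.get("blue"):
            assert min(modules["turquoise"]) < min(modules["blue"])


class TestModuleEigengenes:
    def test_identical_genes_rank_one(self):
        rng = np.random.default_rng(3)
        profile = rng.standard_normal(30)
        values = np.vstack([profile * s + m for s, m in
                            [(1.0, 0.0), (2.0, 1.0), (0.5, -2.0)]])
        expr = cd.ExpressionMatrix(("A", "B", "C"),
                                   tuple(f"S{i}" for i in range(30)), values)
        assignment = cd.ModuleAssignment({g: "blue" for g in expr.gene_ids})
        me = cd.module_eigengenes(expr, assignment)
        zp = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(me.eigengenes["blue"], zp)[0, 1]) == \
            pytest.approx(1.0, abs=1e-10)
        assert me.variance_explained["blue"] == pytest.approx(1.0, abs=1e-10)

    def test_factor_recovery(self, detected):
        expr, traits, truth, assignment, me = detected
        # the dominant eigengene of a planted module tracks its factor:
        # reconstruct the factor as the mean of the module's standardized genes
        label, genes = max(assignment.modules().items(), key=lambda kv: len(kv[1]))
        sub = expr.subset_genes(genes).values
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        proxy = z.mean(axis=0)
        assert abs(np.corrcoef(me.eigengenes[label], proxy)[0, 1]) >= 0.95

    def test_sign_contract(self, detected):
        expr, _, _, assignment, me = detected
        for label, genes in assignment.modules().items():
            sub = expr.subset_genes(genes).values
            z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
            assert np.corrcoef(me.eigengenes[label], z.mean(0))[0, 1] >= 0

    def test_variance_explained_beats_mean_profile(self, detected):
        expr, _, _, assignment, me = detected
        for label, genes in assignment.modules().items():
            sub = expr.subset_genes(genes).values
            z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
            mean_profile = z.mean(axis=0)
            mean_profile /= np.linalg.norm(mean_profile)
            explained_by_mean = np.sum((z @ mean_profile) ** 2) / np.sum(z ** 2)
            assert me.variance_explained[label] >= explained_by_mean - 1e-12


class TestModuleTrait:
    def _me(self, eig, n=20):
        return cd.ModuleEigengenes(
            tuple(f"S{i}" for i in range(n)), {"blue": eig},
            {"blue": 1.0}, {"blue": 10},
        )

    def test_eigengene_equal_to_trait(self):
        labels = np.array([1] * 10 + [0] * 10)
        me = self._me(labels.astype(float))
        traits = cd.TraitVector(tuple(f"S{i}" for i in range(20)), labels)
        table = cd.module_trait(me, traits).table
        assert table.loc["blue", "r"] == pytest.approx(1.0)
        assert table.loc["blue", "p"] < 1e-12

    def test_orthogonal_eigengene(self):
        labels = np.array([1] * 10 + [0] * 10)
        eig = np.tile([1.0, -1.0], 10)  # orthogonal to the trait by construction
        me = self._me(eig)
        traits = cd.TraitVector(tuple(f"S{i}" for i in range(20)), labels)
        table = cd.module_trait(me, traits).table
        assert table.loc["blue", "r"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["blue", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_p_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(17)
        labels = rng.integers(0, 2, size=20)
        while labels.sum() < 4 or labels.sum() > 16:
            labels = rng.integers(0, 2, size=20)
        eig = rng.standard_normal(20)
        me = self._me(eig)
        traits = cd.TraitVector(tuple(f"S{i}" for i in range(20)), labels)
        table = cd.module_trait(me, traits).table
        r = np.corrcoef(eig, labels.astype(float))[0, 1]
        t = r * np.sqrt(18 / (1 - r * r))
        expected = 2 * stats.t.sf(abs(t), df=18)
        assert table.loc["blue", "p"] == pytest.approx(expected, abs=1e-10)

    def test_constant_trait_rejected(self):
        me = self._me(np.arange(20.0))
        labels = np.ones(20, dtype=int)
        with pytest.raises(ValueError):
            traits = cd.TraitVector(tuple(f"S{i}" for i in range(20)), labels)
            cd.module_trait(me, traits)


class TestGeneSignificanceMM:
    def test_gene_equal_to_eigengene_has_mm_one(self, detected):
        expr, traits, _, assignment, me = detected
        stats_out = cd.gene_significance_mm(expr, traits, me, assignment)
        assert (stats_out.mm <= 1.0 + 1e-12).all()
        assert (stats_out.gs <= 1.0 + 1e-12).all()

    def test_background_genes_low_gs(self, detected):
        expr, traits, truth, assignment, me = detected
        stats_out = cd.gene_significance_mm(expr, traits, me, assignment)
        background = [g for g, m in truth.module_of_gene.items() if m == 0]
        assert (stats_out.gs.loc[background] < 0.2).mean() > 0.95

    def test_trait_linked_module_gs_mm_coupled(self, detected):
        expr, traits, truth, assignment, me = detected
        stats_out = cd.gene_significance_mm(expr, traits, me, assignment)
        # the module carrying most of a trait-linked planted module must
        # show coupled GS and MM across members
        best = max(stats_out.gs_mm_correlation.items(), key=lambda kv: kv[1])
        assert best[1] > 0.5


class TestSelectKeyModules:
    def _table(self, rows):
        import pandas as pd
        df = pd.DataFrame(rows, columns=["module", "r", "p", "n_samples",
                                         "n_genes"]).set_index("module")
        return cd.ModuleTraitTable(df)

    def test_published_style_values(self):
        mt = self._table([("blue", 0.88, 2e-78, 238, 100),
                          ("darkred", -0.77, 2e-48, 238, 50),
                          ("green", 0.1, 0.3, 238, 40)])
        assert cd.select_key_modules(mt) == ("blue", "darkred")

    def test_all_positive_requires_allow_single(self):
        mt = self._table([("blue", 0.8, 1e-10, 100, 50),
                          ("red", 0.5, 1e-4, 100, 40)])
        with pytest.raises(ValueError):
            cd.select_key_modules(mt)
        assert cd.select_key_modules(mt, allow_single=True) == ("blue", None)

    def test_tie_broken_by_size(self):
        mt = self._table([("blue", 0.8, 1e-10, 100, 50),
                          ("red", 0.8, 1e-10, 100, 80),
                          ("green", -0.5, 1e-4, 100, 40)])
        assert cd.select_key_modules(mt)[0] == "red"

    def test_no_significant_module_errors(self):
        mt = self._table([("blue", 0.2, 0.4, 100, 50),
                          ("red", -0.1, 0.6, 100, 40)])
        with pytest.raises(ValueError, match="threshold"):
            cd.select_key_modules(mt)
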