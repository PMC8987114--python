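import numpy as np
import pytest
from scipy import stats

import coexdiff as cd
from coexdiff.datasets import (
    GSE134347_N_HEALTHY, GSE134347_N_SEPSIS, GSE134347_TOP_SWITCH_PAIRS,
)


class TestSplitByCondition:
    def test_partition_counts_and_gene_order(self, default_sim):
        expr, traits, _ = default_sim
        cond1, cond2 = cd.split_by_condition(expr, traits)
        assert cond1.n_samples == 150 and cond2.n_samples == 80
        assert cond1.gene_ids == cond2.gene_ids == expr.gene_ids

    def test_small_class_rejected(self, rng):
        ids = tuple(f"S{i}" for i in range(10))
        with pytest.raises(ValueError, match=">= 4"):
            cd.TraitVector(ids, np.array([1] * 7 + [0] * 3))


class TestFisherZTest:
    def test_equal_correlations_null(self):
        z, p = cd.fisher_z_test(0.5, 100, 0.5, 40)
        assert z == 0.0 and p == 1.0

    def test_published_pair_arithmetic_oracle(self):
        # closed-form evaluation of the Fisher z statistic for a worked
        # (r1, n1, r2, n2) input with a large sign switch
        r1, n1, r2, n2 = 0.406621495, 156, -0.728163034, 82
        z, p = cd.fisher_z_test(r1, n1, r2, n2)
        expected = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / 153 + 1 / 79)
        assert z == pytest.approx(expected, abs=1e-12)
        assert p < 1e-15

    def test_antisymmetry(self):
        z1, p1 = cd.fisher_z_test(0.3, 50, -0.4, 70)
        z2, p2 = cd.fisher_z_test(-0.4, 70, 0.3, 50)
        assert z1 == pytest.approx(-z2, abs=1e-14)
        assert p1 == pytest.approx(p2, abs=1e-16)

    def test_unit_correlation_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z, p = cd.fisher_z_test(1.0, 50, 0.0, 50)
        assert np.isfinite(z)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cd.fisher_z_test(1.5, 50, 0.0, 50)


class TestCorrelationP:
    def test_null(self):
        assert cd.correlation_p(0.0, 30) == 1.0

    def test_extreme(self):
        assert cd.correlation_p(0.99, 100) < 1e-10

    @pytest.mark.parametrize("r", [-0.8, -0.3, 0.1, 0.5, 0.9])
    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_t_cdf_oracle(self, r, n):
        t = r * np.sqrt((n - 2) / (1 - r * r))
        expected = 2 * stats.t.sf(abs(t), df=n - 2)
        assert cd.correlation_p(r, n) == pytest.approx(expected, abs=1e-10)


class TestLocalFdr:
    def test_null_calibration(self):
        fractions, means = [], []
        for seed in range(10):
            z = np.random.default_rng(seed).standard_normal(5000)
            lfdr, diag = cd.local_fdr(z)
            assert diag.method == "spline"
            fractions.append((lfdr < 0.05).mean())
            means.append(lfdr.mean())
        assert np.mean(means) >= 0.9
        assert np.mean(fractions) <= 0.01

    def test_mixture_detection(self):
        rng = np.random.default_rng(42)
        null = rng.standard_normal(4750)
        shifted = rng.normal(6.0, 1.0, size=250)
        lfdr, _ = cd.local_fdr(np.concatenate([null, shifted]))
        assert (lfdr[4750:] < 0.05).mean() > 0.9

    def test_degenerate_input_falls_back_to_bh(self, caplog):
        with caplog.at_level("WARNING", logger="coexdiff"):
            lfdr, diag = cd.local_fdr(np.zeros(500))
        assert diag.method == "bh_fallback"

    def test_small_input_falls_back_to_bh(self, caplog):
        with caplog.at_level("WARNING", logger="coexdiff"):
            _, diag = cd.local_fdr(np.arange(10.0))
        assert diag.method == "bh_fallback"

    def test_monotone_in_abs_z(self):
        z = np.random.default_rng(1).standard_normal(2000)
        lfdr, _ = cd.local_fdr(z)
        order = np.argsort(np.abs(z))
        assert np.all(np.diff(lfdr[order]) <= 1e-12)


class TestDiffcorrScan:
    def test_planted_switch_pairs_recovered(self, switch_sim):
        expr, traits, truth = switch_sim
        cond1, cond2 = cd.split_by_condition(expr, traits)
        table = cd.diffcorr_scan(cond1, cond2, expr.gene_ids)
        flagged = {frozenset((r.gene_a, r.gene_b))
                   for r in cd.switched_pairs(table, 0.05)}
        planted = {frozenset(p) for p in truth.switch_pairs}
        assert len(planted & flagged) >= 9

    def test_identical_conditions_all_null(self, default_sim):
        expr, _, _ = default_sim
        sub = expr.subset_genes(expr.gene_ids[:20])
        table = cd.diffcorr_scan(sub, sub)
        assert all(r.z_stat == 0.0 for r in table.records)

    def test_pair_count(self, default_sim):
        expr, traits, _ = default_sim
        cond1, cond2 = cd.split_by_condition(expr, traits)
        table = cd.diffcorr_scan(cond1, cond2, expr.gene_ids[:5])
        assert len(table.records) == 10

    def test_condition_exchange_antisymmetry(self, switch_sim):
        expr, traits, _ = switch_sim
        cond1, cond2 = cd.split_by_condition(expr, traits)
        genes = expr.gene_ids[:15]
        fwd = cd.diffcorr_scan(cond1, cond2, genes)
        rev = cd.diffcorr_scan(cond2, cond1, genes)
        fwd_by_pair = {(r.gene_a, r.gene_b): r for r in fwd.records}
        for r in rev.records:
            f = fwd_by_pair[(r.gene_a, r.gene_b)]
            assert r.z_stat == pytest.approx(-f.z_stat, abs=1e-12)
            assert r.p_diff == pytest.approx(f.p_diff, abs=1e-15)
            assert r.switched == f.switched

    def test_sorted_by_lfdr_then_abs_z(self, switch_sim):
        expr, traits, _ = switch_sim
        cond1, cond2 = cd.split_by_condition(expr, traits)
        table = cd.diffcorr_scan(cond1, cond2, expr.gene_ids)
        keys = [(r.lfdr, -abs(r.z_stat)) for r in table.records]
        assert keys == sorted(keys)

    def test_zero_variance_gene_excluded(self, default_sim, caplog):
        expr, traits, _ = default_sim
        values = expr.values.copy()
        values[0] = 3.14
        flat = cd.ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)
        cond1, cond2 = cd.split_by_condition(flat, traits)
        with caplog.at_level("WARNING", logger="coexdiff"):
            table = cd.diffcorr_scan(cond1, cond2, expr.gene_ids[:10])
        assert expr.gene_ids[0] in table.excluded_genes


class TestSwitchedPairs:
    def _table(self, records):
        from coexdiff.diffcorr import DiffCorrTable, LfdrDiagnostics
        return DiffCorrTable(tuple(records), 150, 80,
                             LfdrDiagnostics("spline", 1.0, 120, len(records)))

    def _rec(self, r1, r2, lfdr):
        return cd.DiffCorrRecord(
            gene_a="A", gene_b="B", r1=r1, n1=150, r2=r2, n2=80,
            p1=0.01, p2=0.01, z_stat=4.0, p_diff=1e-4, lfdr=lfdr,
            switched=r1 * r2 < 0,
        )

    def test_filter_semantics(self):
        table = self._table([
            self._rec(0.4, -0.7, 0.001),   # retained
            self._rec(0.4, 0.1, 0.001),    # no sign switch
            self._rec(0.4, -0.7, 0.2),     # lfdr too high
        ])
        kept = cd.switched_pairs(table, 0.05)
        assert len(kept) == 1
        assert kept[0].r2 == -0.7


class TestPublishedSwitchPairs:
    """The twenty reported sepsis/healthy switch pairs as worked inputs."""

    @pytest.mark.parametrize("row", GSE134347_TOP_SWITCH_PAIRS,
                             ids=lambda r: f"{r[0]}-{r[1]}")
    def test_each_pair_significant_and_switched(self, row):
        _, _, r1, r2, _ = row
        z, p = cd.fisher_z_test(r1, GSE134347_N_SEPSIS, r2, GSE134347_N_HEALTHY)
        assert r1 * r2 < 0
        assert p < 0.05
        assert abs(z) > 5


class TestEigenMoleculeNetwork:
    def _two_factor_expr(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.standard_normal((2, n))
        genes, values = [], []
        for i in range(20):
            f = f1 if i < 10 else f2
            genes.append(f"G{i:02d}")
            values.append(0.9 * f + np.sqrt(1 - 0.81) * rng.standard_normal(n))
        return cd.ExpressionMatrix(tuple(genes),
                                   tuple(f"S{j}" for j in range(n)),
                                   np.vstack(values))

    def test_two_factor_partition(self):
        from sklearn.metrics import adjusted_rand_score
        expr = self._two_factor_expr()
        net = cd.eigen_molecule_network(expr, expr.gene_ids, n_submodules=2)
        truth = [0] * 10 + [1] * 10
        found = np.zeros(20, dtype=int)
        for k, (_, members) in enumerate(net.submodules.items()):
            for g in members:
                found[int(g[1:])] = k
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_edge_threshold_limits(self):
        expr = self._two_factor_expr(seed=5)
        complete = cd.eigen_molecule_network(expr, expr.gene_ids, 3,
                                             edge_threshold=0.0)
        assert len(complete.edges) == 3
        none = cd.eigen_molecule_network(expr, expr.gene_ids, 3,
                                         edge_threshold=1.01)
        assert len(none.edges) == 0

    def test_submodules_partition_module(self):
        expr = self._two_factor_expr(seed=6)
        net = cd.eigen_molecule_network(expr, expr.gene_ids, 4)
        all_members = [g for members in net.submodules.values() for g in members]
        assert sorted(all_members) == sorted(expr.gene_ids)
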