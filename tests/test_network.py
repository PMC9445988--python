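"""Co-expression machinery: adjacency, TOM, modules, eigengenes, GS/kME."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tissuemod import network
from tissuemod.dataset import ConfigError, DataError

from conftest import BUNDLE_POWER, tom_reference


def random_symmetric_adjacency(n, rng):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestTom:
    def test_isolated_perfect_pair(self):
        """Three genes, a_12 = 1, all else 0: T_12 = (0+1)/(1+1-1) = 1."""
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        t = network.tom_from_adjacency(a)
        assert t[0, 1] == pytest.approx(1.0)
        assert t[0, 2] == pytest.approx(0.0)

    def test_matrix_product_equals_triple_loop_on_seeded_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(20, 31))
            a = random_symmetric_adjacency(n, rng)
            np.testing.assert_allclose(network.tom_from_adjacency(a),
                                       tom_reference(a), atol=1e-12)

    def test_identical_genes_with_perfectly_shared_neighbours_have_unit_overlap(self):
        """Genes i, j with identical profiles and a fully shared neighbour
        (all three mutually |r| = 1) reach T_ij = 1; an exactly orthogonal
        bystander gene does not dilute the overlap."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        other = rng.normal(size=12)
        bc = base - base.mean()
        oc = other - other.mean()
        oc -= (oc @ bc) / (bc @ bc) * bc  # exactly decorrelated from base
        X = pd.DataFrame([base, base, 2.0 * base + 1.0, oc],
                         index=["g1", "g2", "g3", "g4"])
        net = network.build_network(X, beta=2)
        assert net.tom[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_unit_diagonal_and_range(self, bundle_modules):
        net, _ = bundle_modules
        for mat in (net.adjacency, net.tom):
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 1.0)
            assert mat.min() >= 0.0 and mat.max() <= 1.0


class TestAdjacency:
    def test_raising_power_shrinks_off_diagonal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 20)))
        a3 = network.build_adjacency(X, 3)
        a5 = network.build_adjacency(X, 5)
        off = ~np.eye(10, dtype=bool)
        assert (a5[off] < a3[off]).all()

    def test_zero_variance_gene_named(self):
        X = pd.DataFrame(np.vstack([np.ones(10), np.random.default_rng(0).normal(size=10)]))
        with pytest.raises(DataError, match="zero-variance"):
            network.build_adjacency(X, 2)

    def test_power_below_one_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ConfigError):
            network.build_adjacency(X, 0.5)


class TestSoftThresholdScan:
    def test_single_power_gives_single_row(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(30, 12)))
        scan = network.scan_soft_thresholds(X, powers=[7])
        assert len(scan) == 1 and scan["power"].iloc[0] == 7

    def test_recommendation_rule_prefers_smallest_power_reaching_target(self):
        """Recommendation = smallest power with signed fit >= target, else
        the argmax; exercised on the bundle matrix scan."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 15)))
        scan = network.scan_soft_thresholds(X, powers=range(1, 11), fit_target=0.8)
        rec = network.recommended_power(scan)
        reaching = scan.loc[scan["fit"] >= 0.8, "power"]
        if len(reaching):
            assert rec == reaching.iloc[0]
        else:
            assert scan.loc[scan["power"] == rec, "fit"].iloc[0] == scan["fit"].max()

    def test_paper_style_fixed_power_overrides_accepted(self):
        # replaying a published configuration: powers scanned 1-20 but the
        # chosen power fixed externally (e.g. 7 / 1 / 14 per disease)
        from tissuemod.config import PipelineConfig

        for override in (7, 1, 14):
            cfg = PipelineConfig(power_override=override)
            cfg.validate()
            assert cfg.power_override == override

    def test_scan_rows_well_formed_and_connectivity_decreases(self, bundle_matrix):
        matrix, _ = bundle_matrix
        scan = network.scan_soft_thresholds(matrix.expr, powers=range(1, 11))
        assert list(scan["power"]) == list(range(1, 11))
        assert scan["fit"].between(-1, 1).all()
        assert (np.diff(scan["mean_connectivity"]) < 0).all()
        assert scan["recommended"].sum() == 1


class TestDetectModules:
    def test_two_perfect_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        f1, f2 = rng.normal(size=20), rng.normal(size=20)
        X = pd.DataFrame(np.vstack([np.outer(np.ones(5), f1),
                                    np.outer(np.ones(5), f2)]),
                         index=[f"g{i}" for i in range(10)])
        X += rng.normal(0, 1e-6, X.shape)
        net = network.build_network(X, 6)
        ms = network.detect_modules(net, min_module_size=5)
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, ms.labels) == 1.0
        assert len(ms.module_ids) == 2

    def test_min_module_size_larger_than_branches_gives_all_grey(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(40, 10)))
        net = network.build_network(X, 6)
        ms = network.detect_modules(net, min_module_size=35)
        assert (ms.labels == 0).all()

    def test_invalid_cut_height_rejected(self):
        rng = np.random.default_rng(1)
        net = network.build_network(pd.DataFrame(rng.normal(size=(40, 10))), 6)
        with pytest.raises(ConfigError):
            network.detect_modules(net, cut_height=1.5)

    def test_default_bundle_recovery(self, bundle_matrix):
        """Planted modules recovered with high agreement on the seed-0
        bundle (the 20-replicate median is asserted in the acceptance
        suite)."""
        matrix, truth = bundle_matrix
        net = network.build_network(matrix.expr, BUNDLE_POWER)
        ms = network.detect_modules(net)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = network.merge_similar_modules(matrix.expr, ms)
        ari = adjusted_rand_score(truth.modules.loc[matrix.expr.index], ms.labels)
        assert ari >= 0.8


class TestEigengenes:
    def test_identical_genes_have_unit_kme(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=15)
        X = pd.DataFrame([base, base, base], index=["a", "b", "c"])
        ms = network.ModuleSet(labels=pd.Series([1, 1, 1], index=X.index))
        ms = network.compute_eigengenes(X, ms)
        np.testing.assert_allclose(ms.kme["ME1"], 1.0, atol=1e-10)

    def test_eigengene_is_leading_variance_direction(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(8, 25)))
        ms = network.compute_eigengenes(
            X, network.ModuleSet(labels=pd.Series(1, index=X.index)))
        Z = ((X - X.mean(axis=1).to_numpy()[:, None])
             / X.std(axis=1).to_numpy()[:, None]).to_numpy()
        me = ms.me["ME1"].to_numpy()
        var_me = ((Z @ me) ** 2).sum()
        for _ in range(50):
            v = rng.normal(size=25)
            v /= np.linalg.norm(v)
            assert ((Z @ v) ** 2).sum() <= var_me + 1e-8

    def test_eigengene_zero_mean_and_unit_norm(self, bundle_modules):
        _, ms = bundle_modules
        me = ms.me.to_numpy()
        np.testing.assert_allclose(me.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(me, axis=0), 1.0, atol=1e-10)

    def test_members_prefer_their_own_module(self, bundle_matrix, bundle_modules):
        """>= 95% of planted-module members have their largest |kME| at the
        detected module that hosts their planted block."""
        matrix, truth = bundle_matrix
        _, ms = bundle_modules
        agree, total = 0, 0
        for g in matrix.expr.index:
            mid = ms.labels[g]
            if mid == 0 or truth.modules[g] == 0:
                continue
            total += 1
            own = abs(ms.kme.loc[g, f"ME{mid}"])
            if own >= ms.kme.loc[g].abs().max() - 1e-12:
                agree += 1
        assert total > 0 and agree / total >= 0.95

    def test_single_gene_module_warns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        ms = network.ModuleSet(labels=pd.Series([1, 0, 0], index=X.index))
        with pytest.warns(UserWarning, match="single gene"):
            network.compute_eigengenes(X, ms)


class TestMergeModules:
    def _two_module_set(self, rho):
        rng = np.random.default_rng(7)
        f1 = rng.normal(size=40)
        f2 = rho * f1 + np.sqrt(1 - rho**2) * rng.normal(size=40)
        X = pd.DataFrame(
            np.vstack([np.outer(rng.uniform(1, 1.2, 10), f1),
                       np.outer(rng.uniform(1, 1.2, 10), f2)])
            + rng.normal(0, 0.05, (20, 40)),
            index=[f"g{i}" for i in range(20)])
        labels = pd.Series([1] * 10 + [2] * 10, index=X.index)
        return X, network.ModuleSet(labels=labels)

    def test_highly_correlated_eigengenes_merged(self):
        X, ms = self._two_module_set(rho=0.95)
        merged = network.merge_similar_modules(X, ms, merge_cut=0.25)
        assert len(merged.module_ids) == 1

    def test_moderately_correlated_eigengenes_kept_apart(self):
        X, ms = self._two_module_set(rho=0.5)
        merged = network.merge_similar_modules(X, ms, merge_cut=0.25)
        assert len(merged.module_ids) == 2

    def test_zero_cut_never_merges(self):
        X, ms = self._two_module_set(rho=0.99)
        merged = network.merge_similar_modules(X, ms, merge_cut=0.0)
        assert len(merged.module_ids) == 2


class TestModuleTissueCorrelation:
    def _set_with_indicator_me(self, r_target, n=50):
        rng = np.random.default_rng(0)
        ind = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        tissue = pd.Series(np.where(ind == 1, "PFC", "CRE"),
                           index=[f"s{i}" for i in range(n)])
        me_vec = r_target * (ind - ind.mean()) / ind.std()
        if abs(r_target) < 1:
            noise = rng.normal(size=n)
            noise -= noise.mean()
            noise -= (noise @ (ind - ind.mean())) / ((ind - ind.mean()) ** 2).sum() * (ind - ind.mean())
            noise /= noise.std()
            me_vec = me_vec + np.sqrt(1 - r_target**2) * noise
        X = pd.DataFrame(np.outer(np.ones(35), me_vec)
                         + rng.normal(0, 1e-9, (35, n)),
                         columns=tissue.index)
        labels = pd.Series(1, index=X.index)
        return X, labels, tissue

    def test_indicator_eigengene_flagged(self):
        X, labels, tissue = self._set_with_indicator_me(1.0)
        ms = network.module_tissue_correlation(
            X, network.ModuleSet(labels=labels), tissue)
        assert ms.module_tissue_r.loc["ME1", "PFC"] == pytest.approx(1.0, abs=1e-6)
        assert ms.module_tissue_p.loc["ME1", "PFC"] < 1e-10
        assert bool(ms.tissue_specific.loc["ME1", "PFC"])

    def test_uncorrelated_eigengene_not_flagged(self):
        X, labels, tissue = self._set_with_indicator_me(0.0)
        ms = network.module_tissue_correlation(
            X, network.ModuleSet(labels=labels), tissue)
        assert abs(ms.module_tissue_r.loc["ME1", "PFC"]) < 0.3
        assert not bool(ms.tissue_specific.loc["ME1", "PFC"])

    def test_p_value_formula_extremes(self):
        """r = 0 gives p = 1 exactly; |r| = 0.999 at n = 50 gives p < 1e-10
        through t = r sqrt((n-2)/(1-r^2))."""
        r, p = network._indicator_correlation(
            np.outer(np.r_[np.ones(25), -np.ones(25)], [1.0]),
            np.r_[np.ones(25), np.zeros(25)])
        assert p[0] < 1e-10
        rng = np.random.default_rng(0)
        from scipy import stats as ss
        t999 = 0.999 * np.sqrt(48 / (1 - 0.999**2))
        assert 2 * ss.t.sf(t999, 48) < 1e-10
        # orthogonal vector -> r = 0 -> p = 1
        ind = np.r_[np.ones(25), np.zeros(25)]
        v = np.r_[np.ones(25), np.ones(25)] * rng.normal()  # constant -> r 0
        vals = (np.r_[np.ones(12), -np.ones(13), np.ones(13), -np.ones(12)])
        r0, p0 = network._indicator_correlation(vals[:, None] * 1.0, ind)
        assert abs(r0[0]) < 0.1 and p0[0] > 0.5

    def test_constant_tissue_indicator_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)))
        tissue = pd.Series("PFC", index=X.columns)
        with pytest.raises(DataError, match="constant"):
            network.module_tissue_correlation(
                X, network.ModuleSet(labels=pd.Series(1, index=X.index)), tissue)

    def test_planted_module_flagged_for_home_tissue_only(self, bundle_matrix,
                                                         bundle_modules):
        matrix, truth = bundle_matrix
        _, ms = bundle_modules
        for me_name in ms.tissue_specific.index:
            mid = int(me_name.removeprefix("ME"))
            genes = ms.module_genes(mid)
            if (truth.modules.loc[genes] == 1).mean() > 0.5:  # planted PFC module
                assert bool(ms.tissue_specific.loc[me_name, "PFC"])
                others = [t for t in ms.tissue_specific.columns if t != "PFC"]
                assert not ms.tissue_specific.loc[me_name, others].any()
                break
        else:
            pytest.fail("no detected module matched the planted PFC module")


class TestScreenModuleGenes:
    def _module_set(self, gs_val, kme_val):
        labels = pd.Series([1, 1], index=["a", "b"])
        ms = network.ModuleSet(
            labels=labels,
            me=pd.DataFrame({"ME1": [0.0]}),
            kme=pd.DataFrame({"ME1": [kme_val, 0.9]}, index=labels.index),
            gs=pd.DataFrame({"PFC": [gs_val, 0.7]}, index=labels.index),
            module_tissue_r=pd.DataFrame({"PFC": [0.9]}, index=["ME1"]),
            module_tissue_p=pd.DataFrame({"PFC": [1e-9]}, index=["ME1"]),
            tissue_specific=pd.DataFrame({"PFC": [True]}, index=["ME1"]),
        )
        return ms

    def test_boundary_gs_excluded_strictly(self):
        table = network.screen_module_genes(self._module_set(0.6, 0.85))
        assert list(table["gene"]) == ["b"]

    def test_passing_gene_included(self):
        table = network.screen_module_genes(self._module_set(0.7, 0.85))
        assert set(table["gene"]) == {"a", "b"}

    def test_thresholds_configurable(self):
        table = network.screen_module_genes(self._module_set(0.5, 0.7),
                                            gs_min=0.4, kme_min=0.6)
        assert set(table["gene"]) == {"a", "b"}


class TestTissueDendrogram:
    def test_identical_profiles_merge_at_zero_height(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=30)
        X = pd.DataFrame(np.column_stack([prof, prof, rng.normal(size=30)]),
                         columns=["s1", "s2", "s3"])
        tissue = pd.Series(["A", "B", "C"], index=X.columns)
        nwk = network.tissue_dendrogram(X, tissue)
        from skbio.tree import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(nwk))
        a = tree.find("A")
        sib = [t.name for t in a.siblings()]
        assert "B" in sib
        assert a.length == pytest.approx(0.0, abs=1e-9)

    def test_newick_parses_and_covers_all_tissues(self, bundle_matrix):
        matrix, _ = bundle_matrix
        nwk = network.tissue_dendrogram(matrix.expr, matrix.tissue_labels)
        from skbio.tree import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(nwk))
        tips = {t.name for t in tree.tips()}
        assert tips == set(matrix.tissue_labels.unique())

    def test_tissues_sharing_a_factor_cluster_together(self):
        """A module active in both HPC and STR makes those tissues siblings."""
        from tissuemod.simulate import PlantedModule, SimulationConfig, simulate_study
        from tissuemod.pipeline import network_matrix_from_bundle

        cfg = SimulationConfig(
            n_tissues=8, datasets_per_tissue=1, n_genes=120,
            planted_modules=(
                PlantedModule(1, 40, ("HPC", "STR"), 2.5, 2.0),),
            n_de_genes=0, confounders=(), seed=2)
        datasets, _ = simulate_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix = network_matrix_from_bundle(datasets)
        nwk = network.tissue_dendrogram(matrix.expr, matrix.tissue_labels)
        from skbio.tree import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(nwk))
        hpc = tree.find("HPC")
        assert "STR" in [t.name for t in hpc.siblings()]
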