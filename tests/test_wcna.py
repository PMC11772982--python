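"""Network construction, module detection, eigengenes and trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sulcalvar.config import NetworkParams
from sulcalvar.wcna import (
    build_network,
    detect_modules,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    partial_correlation,
    pick_soft_threshold,
    remove_outlier,
    signed_hybrid_adjacency,
    tom_similarity,
)


def block_profiles(rng, n=60, sizes=(25, 25), noise=0.3, extra=5):
    """Participant profiles with duplicated-column blocks plus noise."""
    cols = {}
    idx = 0
    for b, size in enumerate(sizes):
        base = rng.standard_normal(n)
        for _ in range(size):
            cols[f"b{b}_{idx}"] = base + noise * rng.standard_normal(n)
            idx += 1
    for e in range(extra):
        cols[f"noise_{e}"] = rng.standard_normal(n)
    return pd.DataFrame(cols)


class TestAdjacency:
    @pytest.mark.parametrize("cor,power,expected", [
        (1.0, 6, 1.0),
        (-0.5, 6, 0.0),
        (0.5, 9, 0.001953125),
    ])
    def test_signed_hybrid_rule(self, cor, power, expected):
        c = np.array([[1.0, cor], [cor, 1.0]])
        adj = signed_hybrid_adjacency(c, power)
        assert adj[0, 1] == pytest.approx(expected)
        assert adj[0, 0] == 0.0

    def test_invalid_power(self):
        with pytest.raises(ValueError):
            signed_hybrid_adjacency(np.eye(2), 0)


class TestTOM:
    def test_three_node_hand_formula(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = tom_similarity(a)
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_zero_adjacency(self):
        tom = tom_similarity(np.zeros((4, 4)))
        off = tom[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_duplicate_neighborhoods_full_overlap(self):
        # unit-weight duplicate nodes with identical neighbors
        a = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_hand_formula_on_three_node_cases(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 1, size=(3, 3))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_similarity(a)
            k = a.sum(axis=1)
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    u = 3 - i - j
                    expected = (a[i, u] * a[u, j] + a[i, j]) / (
                        min(k[i], k[j]) + 1 - a[i, j])
                    assert tom[i, j] == pytest.approx(expected, abs=1e-12)
            assert np.all((tom >= -1e-12) & (tom <= 1 + 1e-12))

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_similarity(a)


class TestSoftThreshold:
    def test_returns_power_in_candidate_range(self, rng):
        profiles = block_profiles(rng, n=60)
        beta, table = pick_soft_threshold(profiles, range(1, 21))
        assert 1 <= beta <= 20
        assert set(table.columns) == {"power", "signed_r2", "mean_k"}

    def test_smallest_qualifying_power_rule(self, rng):
        profiles = block_profiles(rng, n=80)
        _, table = pick_soft_threshold(profiles, range(1, 13))
        qualifying = table[table["signed_r2"] >= 0.8]
        if len(qualifying):
            beta, _ = pick_soft_threshold(profiles, range(1, 13))
            assert beta == int(qualifying["power"].iloc[0])

    def test_block_constant_adjacency_computable(self, rng):
        base1 = rng.standard_normal(30)
        base2 = rng.standard_normal(30)
        profiles = pd.DataFrame(
            {**{f"a{i}": base1 for i in range(6)},
             **{f"b{i}": base2 for i in range(6)}})
        beta, table = pick_soft_threshold(profiles, [1, 2, 3])
        assert np.isfinite(table["mean_k"]).all()


class TestDetectModules:
    def test_two_planted_blocks(self, rng):
        profiles = block_profiles(rng, n=80, sizes=(25, 25), extra=5)
        cor = profiles.corr().to_numpy()
        adj = signed_hybrid_adjacency(cor, 6)
        labels = detect_modules(1 - tom_similarity(adj), profiles.columns,
                                NetworkParams(min_module_size=20))
        non_grey = labels[labels != "grey"]
        assert non_grey.nunique() == 2
        assert (labels == "grey").sum() <= 5
        # members of one block share a label
        block0 = [c for c in profiles.columns if c.startswith("b0")]
        assert labels[block0].nunique() == 1

    def test_all_dissimilar_goes_grey(self):
        d = np.ones((30, 30))
        np.fill_diagonal(d, 0.0)
        labels = detect_modules(d, [f"a{i}" for i in range(30)],
                                NetworkParams(min_module_size=5,
                                              cut_height=0.995))
        assert set(labels) == {"grey"}

    def test_permutation_invariance_up_to_relabeling(self, rng):
        profiles = block_profiles(rng, n=60, sizes=(15, 15), extra=4)
        params = NetworkParams(min_module_size=10)

        def labels_of(p):
            cor = p.corr().to_numpy()
            d = 1 - tom_similarity(signed_hybrid_adjacency(cor, 6))
            return detect_modules(d, p.columns, params)

        l1 = labels_of(profiles)
        perm = rng.permutation(profiles.shape[1])
        l2 = labels_of(profiles.iloc[:, perm])
        joined = pd.crosstab(l1, l2.reindex(l1.index))
        # each original module maps onto exactly one permuted module
        assert ((joined > 0).sum(axis=1) == 1).all()


class TestEigengene:
    def test_identical_columns(self, rng):
        col = rng.standard_normal(20)
        profiles = pd.DataFrame({"a": col, "b": col})
        eig, ve = module_eigengene(profiles)
        assert ve == pytest.approx(1.0)
        z = (col - col.mean()) / col.std(ddof=0)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)

    def test_member_order_invariance(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((15, 6)),
                                columns=list("abcdef"))
        e1, _ = module_eigengene(profiles)
        e2, _ = module_eigengene(profiles[list("fedcba")])
        assert np.allclose(e1, e2, atol=1e-9)

    def test_variance_explained_matches_eigendecomposition(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((25, 5)))
        _, ve = module_eigengene(profiles)
        z = (profiles - profiles.mean()) / profiles.std(ddof=0)
        eigvals = np.linalg.eigvalsh(np.cov(z.to_numpy().T, ddof=0))
        assert ve == pytest.approx(eigvals.max() / eigvals.sum(), abs=1e-9)

    def test_orientation_positive_mean_correlation(self, rng):
        base = rng.standard_normal(30)
        profiles = pd.DataFrame({
            f"m{i}": base + 0.2 * rng.standard_normal(30) for i in range(4)})
        eig, _ = module_eigengene(profiles)
        cors = [np.corrcoef(eig, profiles[c])[0, 1]
                for c in profiles.columns]
        assert np.mean(cors) > 0


class TestMergeModules:
    def build(self, rng, cor_target):
        base = rng.standard_normal(200)
        other = (cor_target * base
                 + np.sqrt(1 - cor_target ** 2) * rng.standard_normal(200))
        cols = {}
        for i in range(5):
            cols[f"x{i}"] = base + 0.05 * rng.standard_normal(200)
        for i in range(5):
            cols[f"y{i}"] = other + 0.05 * rng.standard_normal(200)
        profiles = pd.DataFrame(cols)
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=profiles.columns)
        return profiles, labels

    def test_highly_correlated_modules_merged(self, rng):
        profiles, labels = self.build(rng, 0.9)
        merged = merge_modules(profiles, labels, 0.25)
        assert merged.nunique() == 1

    def test_weakly_correlated_modules_kept(self, rng):
        profiles, labels = self.build(rng, 0.5)
        merged = merge_modules(profiles, labels, 0.25)
        assert merged.nunique() == 2

    def test_idempotent(self, rng):
        profiles, labels = self.build(rng, 0.9)
        once = merge_modules(profiles, labels, 0.25)
        twice = merge_modules(profiles, once, 0.25)
        assert (once == twice).all()


class TestModuleTrait:
    def test_student_p_formula(self, rng):
        # r = 0.73, n = 29 -> t = 5.55, df = 27, p on the order of 1e-5
        r, n = 0.73, 29
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
        p = 2 * stats.t.sf(t, df=n - 2)
        assert t == pytest.approx(5.55, abs=0.01)
        assert 1e-6 < p < 1e-4

    def test_grid_size_and_threshold(self, rng):
        # 22 module summaries x 50 traits -> 1100 cells, 0.05/1100
        from sulcalvar.wcna import Module, ModuleNetwork
        net = ModuleNetwork(params=NetworkParams(), labels=pd.Series())
        participants = [f"p{i}" for i in range(30)]
        for m in range(22):
            eig = pd.Series(rng.standard_normal(30), index=participants)
            net.modules[f"M{m}"] = Module(label=f"M{m}", members=[],
                                          eigengene=eig)
        traits = pd.DataFrame(rng.uniform(0, 1, size=(30, 50)),
                              index=participants,
                              columns=[f"t{i}" for i in range(50)])
        grid = module_trait_correlation(net, traits)
        assert len(grid) == 1100
        assert grid.attrs["bonferroni_threshold"] == \
            pytest.approx(4.54e-5, rel=2e-3)

    def test_pvalues_match_permutation_null(self, rng):
        x = pd.Series(rng.standard_normal(25))
        y = pd.Series(rng.standard_normal(25))
        r, p = partial_correlation(x, y, None)
        perm_more_extreme = 0
        n_perm = 2000
        for _ in range(n_perm):
            rp = np.corrcoef(x, rng.permutation(y.to_numpy()))[0, 1]
            if abs(rp) >= abs(r):
                perm_more_extreme += 1
        p_perm = perm_more_extreme / n_perm
        assert p == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm / n_perm)
                                  + 0.02)


class TestPartialCorrelation:
    def test_identical_series_full_correlation(self, rng):
        x = pd.Series(rng.standard_normal(30))
        cov = pd.DataFrame({"age": rng.standard_normal(30)})
        r, p = partial_correlation(x, x.copy(), cov)
        assert r == pytest.approx(1.0)

    def test_covariate_only_trait_decorrelated(self, rng):
        n = 200
        cov = pd.DataFrame({
            "age": rng.standard_normal(n),
            "edu": rng.standard_normal(n)})
        x = pd.Series(rng.standard_normal(n))
        y = pd.Series(2 * cov["age"] - cov["edu"])
        r, _ = partial_correlation(x, y, cov)
        assert abs(r) < 0.15

    def test_no_covariates_reduces_to_pearson(self, rng):
        x = pd.Series(rng.standard_normal(40))
        y = pd.Series(rng.standard_normal(40))
        r, _ = partial_correlation(x, y, None)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_collinear_covariates_rejected(self, rng):
        x = pd.Series(rng.standard_normal(20))
        y = pd.Series(rng.standard_normal(20))
        age = rng.standard_normal(20)
        cov = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(ValueError):
            partial_correlation(x, y, cov)


class TestRemoveOutlier:
    def test_distant_row_removed(self):
        profiles = pd.DataFrame(
            np.vstack([np.zeros((9, 4)), np.full((1, 4), 50.0)]),
            index=[f"p{i}" for i in range(10)])
        kept, removed = remove_outlier(profiles)
        assert removed == "p9"
        assert len(kept) == 9

    def test_study_design_size(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((30, 8)),
                                index=[f"p{i:02d}" for i in range(30)])
        kept, _ = remove_outlier(profiles)
        assert len(kept) == 29

    def test_row_order_invariance(self, rng):
        profiles = pd.DataFrame(rng.standard_normal((12, 5)),
                                index=[f"p{i:02d}" for i in range(12)])
        profiles.iloc[3] += 20
        _, removed1 = remove_outlier(profiles)
        _, removed2 = remove_outlier(profiles.sample(frac=1, random_state=0))
        assert removed1 == removed2 == "p03"


def test_planted_modules_recovered_end_to_end(rng):
    profiles = block_profiles(rng, n=120, sizes=(25, 25), noise=0.5,
                              extra=10)
    net = build_network(profiles, NetworkParams(power=6), drop_outlier=False)
    non_grey = sorted(set(net.labels) - {"grey"})
    assert len(non_grey) == 2
    for b in (0, 1):
        block = [c for c in profiles.columns if c.startswith(f"b{b}")]
        assert net.labels[block].nunique() == 1
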