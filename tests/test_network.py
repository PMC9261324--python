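import numpy as np
import pandas as pd
import pytest
from scipy import linalg
from sklearn.metrics import adjusted_rand_score

from agecoex.containers import TraitTable
from agecoex.network import (
    CoexpressionNetwork,
    ModulePartition,
    cut_modules,
    gene_significance_and_membership,
    merge_close_modules,
    module_eigengene,
    module_trait_correlation,
    pairwise_correlation,
    pick_soft_threshold,
    scale_free_fit,
    soft_adjacency,
    tom_similarity,
)
from agecoex.simulate import default_modules, generate_cohort

from conftest import make_matrix


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Literal double-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestCorrelation:
    def test_duplicate_and_negated_genes(self):
        x = np.arange(6.0)
        m = make_matrix([x, x, -x])
        cor = pairwise_correlation(m).to_numpy()
        assert cor[0, 1] == pytest.approx(1.0)
        assert cor[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_covariance_computation(self, rng):
        m = make_matrix(rng.standard_normal((10, 20)))
        cor = pairwise_correlation(m).to_numpy()
        v = m.values
        vc = v - v.mean(axis=1, keepdims=True)
        direct = (vc @ vc.T) / np.outer(
            np.sqrt((vc**2).sum(axis=1)), np.sqrt((vc**2).sum(axis=1))
        )
        np.testing.assert_allclose(cor, direct, atol=1e-12)

    def test_zero_variance_gene_listed(self):
        m = make_matrix([[1, 1, 1], [1, 2, 3]], genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pairwise_correlation(m)


class TestSoftAdjacency:
    @pytest.mark.parametrize(
        "r,beta,mode,expected",
        [
            (0.5, 2, "unsigned", 0.25),
            (-0.5, 2, "unsigned", 0.25),
            (-0.5, 2, "signed", 0.0625),
            (1.0, 7, "unsigned", 1.0),
        ],
    )
    def test_definitional_values(self, r, beta, mode, expected):
        cor = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = soft_adjacency(cor, beta, mode)
        assert adj.loc["a", "b"] == pytest.approx(expected)
        assert adj.loc["a", "a"] == 1.0

    def test_beta_below_one_rejected(self):
        cor = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            soft_adjacency(cor, 0)


def _power_law_fake_adjacency(n_bins=5):
    """Rows whose connectivities make bin frequency exactly proportional 1/k."""
    ks, rows = [], []
    for b in range(n_bins):
        k = (b + 1) / 10.0
        count = 60 // (b + 1)
        ks += [k] * count
    n = len(ks)
    a = np.zeros((n, n))
    for i, k in enumerate(ks):
        a[i, (i + 1) % n] = k
    return pd.DataFrame(a)


class TestScaleFreeFit:
    def test_exact_inverse_power_law(self):
        adj = _power_law_fake_adjacency()
        r2, slope = scale_free_fit(adj, n_bins=5)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_two_nonempty_bins_fit_perfectly(self):
        a = np.zeros((20, 20))
        for i in range(20):
            a[i, (i + 1) % 20] = 0.1 if i < 15 else 0.9
        r2, slope = scale_free_fit(pd.DataFrame(a), n_bins=2)
        assert r2 == pytest.approx(1.0)
        assert slope < 0

    def test_equal_connectivities_return_zero_with_warning(self, caplog):
        cor = pd.DataFrame(np.full((5, 5), 0.5) + 0.5 * np.eye(5))
        with caplog.at_level("WARNING", logger="agecoex"):
            r2, slope = scale_free_fit(soft_adjacency(cor, 2))
        assert (r2, slope) == (0.0, 0.0)
        assert "connectivities" in caplog.text


def _power_law_correlation(n=300, seed=0):
    """Rank-1 correlation r_ij = h_i h_j with power-law-ish hubness."""
    rng = np.random.default_rng(seed)
    h = rng.uniform(0.05, 1.0, n) ** 2
    r = np.outer(h, h)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r)


class TestPickSoftThreshold:
    def test_scale_free_structure_reaches_target(self):
        cor = _power_law_correlation()
        beta, table = pick_soft_threshold(cor, list(range(1, 13)), target=0.8)
        row = table[table.beta == beta].iloc[0]
        assert row.r_squared > 0.8 and row.slope < 0
        # smallest qualifying candidate is returned
        qualifying = table[(table.r_squared > 0.8) & (table.slope < 0)]
        assert beta == int(qualifying.beta.iloc[0])

    def test_single_candidate_returned_regardless(self):
        cor = _power_law_correlation(n=50, seed=1)
        beta, table = pick_soft_threshold(cor, [6], target=0.99)
        assert beta == 6 and len(table) == 1

    def test_modular_cohort_falls_back_with_warning(self, caplog):
        m, _ = generate_cohort(200, default_modules(5, 30), 40, seed=0)
        cor = pairwise_correlation(m)
        with caplog.at_level("WARNING", logger="agecoex"):
            beta, table = pick_soft_threshold(cor, [2, 4, 6], target=0.99)
        assert beta in (2, 4, 6)
        assert "falling back" in caplog.text


class TestTOM:
    def test_complete_unit_graph_all_ones(self):
        for n in (3, 4, 7):
            adj = pd.DataFrame(np.ones((n, n)))
            tom = tom_similarity(adj).to_numpy()
            np.testing.assert_allclose(tom, 1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        adj = pd.DataFrame(np.eye(5))
        tom = tom_similarity(adj).to_numpy()
        np.testing.assert_allclose(tom, np.eye(5))

    def test_three_node_path_hand_value(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.5
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 2] == pytest.approx(1 / 6)
        assert tom[0, 1] == pytest.approx((0 + 0.5) / (0.5 + 1 - 0.5))

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(3):
            r = rng.uniform(0, 1, (30, 30))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            ref = tom_bruteforce(a)
            np.testing.assert_allclose(tom, ref, atol=1e-12)
            assert tom.min() >= 0 and tom.max() <= 1


def _block_tom(sizes, within, between, rng):
    n = sum(sizes)
    t = np.full((n, n), between) + rng.uniform(-0.02, 0.02, (n, n))
    t = (t + t.T) / 2
    start = 0
    for s in sizes:
        t[start : start + s, start : start + s] = within + rng.uniform(
            -0.02, 0.02, (s, s)
        )
        start += s
    t = np.clip((t + t.T) / 2, 0, 1)
    np.fill_diagonal(t, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(t, index=genes, columns=genes)


class TestCutModules:
    def test_planted_blocks_recovered_exactly(self, rng):
        tom = _block_tom([40, 40], 0.9, 0.05, rng)
        part = cut_modules(tom, min_module_size=30)
        truth = ["A"] * 40 + ["B"] * 40
        assert len(part.modules()) == 2
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_null_tom_yields_at_most_one_module(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = rng.uniform(0, 0.1, (50, 50))
            t = (t + t.T) / 2
            np.fill_diagonal(t, 1.0)
            part = cut_modules(pd.DataFrame(t), min_module_size=30)
            assert len(part.modules()) <= 1

    def test_min_size_above_gene_count_all_unassigned(self, rng):
        tom = _block_tom([20], 0.9, 0.05, rng)
        part = cut_modules(tom, min_module_size=21)
        assert (part.labels == "unassigned").all()

    def test_quantile_method_recovers_clean_blocks(self, rng):
        tom = _block_tom([40, 40], 0.9, 0.05, rng)
        part = cut_modules(tom, min_module_size=30, cut_quantile=0.99, method="quantile")
        truth = ["A"] * 40 + ["B"] * 40
        assert adjusted_rand_score(truth, part.labels.to_numpy()) == 1.0

    def test_labels_deterministic_size_ordered(self, rng):
        tom = _block_tom([60, 40], 0.9, 0.05, rng)
        part = cut_modules(tom, min_module_size=30)
        assert part.modules() == ["turquoise", "blue"]
        assert len(part.module_genes("turquoise")) == 60


class TestModuleEigengene:
    def _partition(self, m, label="mod"):
        return ModulePartition(
            pd.Series([label] * m.n_genes, index=m.gene_ids), min_module_size=1
        )

    def test_identical_genes_reproduce_common_profile(self, rng):
        profile = rng.standard_normal(12)
        m = make_matrix(np.tile(profile, (5, 1)))
        me = module_eigengene(m, self._partition(m))
        e = me.eigengenes.iloc[0].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(e, z, atol=1e-8)
        assert me.variance_explained.iloc[0] == pytest.approx(1.0)

    def test_antipodal_pair_sign_convention(self, rng):
        x = rng.standard_normal(10)
        m = make_matrix([x, -x])
        me = module_eigengene(m, self._partition(m))
        assert me.variance_explained.iloc[0] == pytest.approx(1.0)
        e = me.eigengenes.iloc[0].to_numpy()
        mean_profile = ((x - x.mean()) / x.std() + (-x + x.mean()) / x.std()) / 2
        # mean profile is ~0; convention only requires non-negative correlation
        assert e.std() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        m = make_matrix(rng.standard_normal((15, 25)))
        me = module_eigengene(m, self._partition(m))
        v = m.values
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
        evals, evecs = linalg.eigh(z @ z.T)
        top = evecs[:, -1]
        e_ref = top @ z
        e_ref = e_ref / e_ref.std()
        if np.corrcoef(e_ref, z.mean(axis=0))[0, 1] < 0:
            e_ref = -e_ref
        np.testing.assert_allclose(me.eigengenes.iloc[0].to_numpy(), e_ref, atol=1e-8)
        assert me.variance_explained.iloc[0] == pytest.approx(
            evals[-1] / evals.sum(), abs=1e-10
        )

    def test_eigengene_optimality_over_random_combinations(self, rng):
        m = make_matrix(rng.standard_normal((12, 30)))
        me = module_eigengene(m, self._partition(m))
        v = m.values
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
        total = (z**2).sum()
        best_frac = me.variance_explained.iloc[0]
        for _ in range(1000):
            w = rng.standard_normal(12)
            w /= np.linalg.norm(w)
            proj = w @ z
            assert (proj**2).sum() / total <= best_frac + 1e-10

    def test_singleton_module_is_standardized_gene(self, rng):
        m = make_matrix(rng.standard_normal((1, 9)))
        me = module_eigengene(m, self._partition(m))
        v = m.values[0]
        np.testing.assert_allclose(
            me.eigengenes.iloc[0], (v - v.mean()) / v.std(), atol=1e-12
        )
        assert me.variance_explained.iloc[0] == 1.0


def _chain_modules(c_adj, c_far, n_per=10, n_samples=200, seed=0):
    """Three modules with eigengene correlations (adj, far, adj)."""
    rng = np.random.default_rng(seed)
    gram = np.array([[1, c_adj, c_far], [c_adj, 1, c_adj], [c_far, c_adj, 1]])
    e = np.linalg.cholesky(gram) @ rng.standard_normal((3, n_samples))
    rows, labels = [], []
    for k, name in enumerate(["A", "B", "C"]):
        for i in range(n_per):
            rows.append(e[k] + rng.normal(0, 0.01, n_samples))
            labels.append(name)
    genes = [f"g{i}" for i in range(len(rows))]
    m = make_matrix(np.array(rows), genes=genes)
    part = ModulePartition(pd.Series(labels, index=genes), min_module_size=1)
    return m, part


class TestMergeModules:
    def test_identical_eigengenes_merge(self, rng):
        e = rng.standard_normal(30)
        rows = [e + rng.normal(0, 0.01, 30) for _ in range(10)]
        m = make_matrix(np.array(rows))
        part = ModulePartition(
            pd.Series(["A"] * 5 + ["B"] * 5, index=m.gene_ids), min_module_size=1
        )
        merged, me = merge_close_modules(m, part, cut_height=0.2)
        assert len(merged.modules()) == 1

    def test_uncorrelated_modules_unchanged(self, rng):
        e1, e2 = rng.standard_normal((2, 200))
        rows = [e1] * 5 + [e2] * 5
        rows = [r + rng.normal(0, 0.01, 200) for r in rows]
        m = make_matrix(np.array(rows))
        part = ModulePartition(
            pd.Series(["A"] * 5 + ["B"] * 5, index=m.gene_ids), min_module_size=1
        )
        merged, me = merge_close_modules(m, part, cut_height=0.2)
        assert len(merged.modules()) == 2

    def test_chain_merges_iteratively_and_terminates(self):
        m, part = _chain_modules(c_adj=0.93, c_far=0.73)
        merged, me = merge_close_modules(m, part, cut_height=0.2)
        assert len(merged.modules()) == 1

    def test_raising_cut_height_never_increases_module_count(self):
        m, part = _chain_modules(c_adj=0.85, c_far=0.45)
        counts = []
        for cut in (0.05, 0.2, 0.5):
            merged, _ = merge_close_modules(m, part, cut_height=cut)
            counts.append(len(merged.modules()))
        assert counts == sorted(counts, reverse=True)


class TestModuleTrait:
    def test_me_equal_to_age_gives_r_one(self, simple_traits):
        from agecoex.network import EigengeneMatrix

        me = EigengeneMatrix(pd.DataFrame([simple_traits.age], index=["m"],
                                          columns=simple_traits.sample_ids),
                             pd.Series({"m": 1.0}))
        mt = module_trait_correlation(me, simple_traits, columns=["age"])
        assert mt.r.iloc[0] == pytest.approx(1.0)
        assert mt.p.iloc[0] <= np.finfo(float).tiny * 10

    def test_orthogonal_me_gives_zero_r(self, simple_traits):
        from agecoex.network import EigengeneMatrix

        age = simple_traits.age
        c = age - age.mean()
        v = np.zeros_like(c)
        v[0], v[1] = c[1], -c[0]  # orthogonal to centred age in first two coords
        me = EigengeneMatrix(pd.DataFrame([v], index=["m"],
                                          columns=simple_traits.sample_ids),
                             pd.Series({"m": 1.0}))
        mt = module_trait_correlation(me, simple_traits, columns=["age"])
        assert mt.r.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert mt.p.iloc[0] == pytest.approx(1.0)

    def test_p_matches_permutation_oracle(self, rng):
        from agecoex.network import EigengeneMatrix, correlation_p

        n = 20
        x = rng.standard_normal(n)
        y = 0.7 * (x - x.mean()) / x.std() + 0.72 * rng.standard_normal(n)
        r_obs = np.corrcoef(x, y)[0, 1]
        p_t = float(correlation_p(np.array([r_obs]), n)[0])
        n_perm = 100_000
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        xz = (x - x.mean()) / x.std()
        pz = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(
            axis=1, keepdims=True
        )
        r_perm = pz @ xz / n
        p_perm = (np.sum(np.abs(r_perm) >= abs(r_obs)) + 1) / (n_perm + 1)
        mc_sd = np.sqrt(p_t * (1 - p_t) / n_perm)
        assert abs(p_perm - p_t) < 5 * mc_sd + 1e-5

    def test_constant_explicit_trait_errors(self, simple_traits):
        from agecoex.network import EigengeneMatrix

        me = EigengeneMatrix(pd.DataFrame([simple_traits.age], index=["m"],
                                          columns=simple_traits.sample_ids),
                             pd.Series({"m": 1.0}))
        t = TraitTable(simple_traits.data.assign(flat="x"))
        with pytest.raises(ValueError, match="flat"):
            module_trait_correlation(me, t, columns=["flat"])


class TestGeneSignificanceMembership:
    def test_gene_equal_to_trait_and_eigengene(self, rng):
        trait = rng.standard_normal(15)
        other = rng.standard_normal(15)
        m = make_matrix([trait, other])
        from agecoex.network import EigengeneMatrix

        me = EigengeneMatrix(
            pd.DataFrame([other], index=["mod"], columns=m.sample_ids),
            pd.Series({"mod": 1.0}),
        )
        gs, mm = gene_significance_and_membership(m, me, trait)
        assert gs.loc["g0", "gs"] == pytest.approx(1.0)
        assert mm.loc["g1", "mod"] == pytest.approx(1.0)

    def test_constant_gene_flagged_excluded(self, rng):
        m = make_matrix([np.ones(10), rng.standard_normal(10)])
        from agecoex.network import EigengeneMatrix

        me = EigengeneMatrix(
            pd.DataFrame([rng.standard_normal(10)], index=["mod"], columns=m.sample_ids),
            pd.Series({"mod": 1.0}),
        )
        gs, mm = gene_significance_and_membership(m, me, np.arange(10.0))
        assert bool(gs.loc["g0", "constant"])
        assert np.isnan(gs.loc["g0", "gs"]) and np.isnan(mm.loc["g0", "mod"])

    def test_own_module_membership_dominates(self):
        for seed in range(5):
            m, truth = generate_cohort(0, default_modules(4, 25), 60, seed=seed)
            part = ModulePartition(pd.Series(truth.gene_module), min_module_size=1)
            me = module_eigengene(m, part)
            gs, mm = gene_significance_and_membership(m, me, truth.traits.age)
            for mod in me.modules:
                genes = part.module_genes(mod)
                own = mm.loc[genes, mod].abs().mean()
                others = [mm.loc[genes, o].abs().mean() for o in me.modules if o != mod]
                assert own > max(others)


class TestModelResults:
    def test_fit_returns_partition_eigengenes_and_summary(self):
        m, truth = generate_cohort(100, default_modules(3, 40), 40, seed=5)
        res = CoexpressionNetwork(m, truth.traits).fit(beta=6)
        assert res.beta == 6
        assert set(res.summary().columns) >= {"module", "n_genes", "variance_explained"}
        assert res.eigengenes.eigengenes.shape[1] == 40
        assert "age" in set(res.module_trait.trait)

    def test_repeated_fits_identical(self):
        m, truth = generate_cohort(100, default_modules(3, 40), 40, seed=5)
        r1 = CoexpressionNetwork(m, truth.traits).fit(beta=6)
        r2 = CoexpressionNetwork(m, truth.traits).fit(beta=6)
        pd.testing.assert_series_equal(r1.partition.labels, r2.partition.labels)
        pd.testing.assert_frame_equal(r1.eigengenes.eigengenes, r2.eigengenes.eigengenes)
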