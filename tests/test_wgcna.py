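import numpy as np
import pandas as pd
import pytest

from dimorph import wgcna
from dimorph.core import log_transform
from dimorph.synth import simulate_bulk_panel
from conftest import make_matrix


def tom_oracle(A):
    """Triple-loop reference implementation of unsigned topological overlap."""
    a = A.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    T = np.eye(n)
    for m in range(n):
        for nn in range(n):
            if m == nn:
                continue
            shared = sum(a[m, u] * a[u, nn] for u in range(n) if u not in (m, nn))
            T[m, nn] = (shared + a[m, nn]) / (min(k[m], k[nn]) + 1 - a[m, nn])
    return T


class TestSimilarity:
    def test_identical_genes(self):
        m = make_matrix([[1, 2, 3], [1, 2, 3]])
        S = wgcna.similarity(m)
        assert S.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_gene_unsigned(self):
        m = make_matrix([[1, 2, 3], [3, 2, 1]])
        S = wgcna.similarity(m)
        assert S.iloc[0, 1] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        m = make_matrix([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="zero-variance"):
            wgcna.similarity(m)

    def test_null_mean_matches_folded_normal(self):
        rng = np.random.default_rng(0)
        n = 1000
        m = make_matrix(rng.random((40, n)))
        S = wgcna.similarity(m).to_numpy()
        off = S[~np.eye(40, dtype=bool)]
        expected = np.sqrt(2 / np.pi) / np.sqrt(n)
        assert off.mean() == pytest.approx(expected, rel=0.2)


class TestAdjacency:
    def test_power_values(self):
        S = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        A = wgcna.adjacency(S, 10)
        assert A.iloc[0, 1] == pytest.approx(0.0009765625)
        assert A.iloc[0, 0] == 0.0  # diagonal zeroed

    def test_beta_one_identity_off_diagonal(self):
        S = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=["a", "b"], columns=["a", "b"])
        A = wgcna.adjacency(S, 1)
        assert A.iloc[0, 1] == pytest.approx(0.3)

    def test_beta_below_one_rejected(self):
        S = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            wgcna.adjacency(S, 0)


class TestSoftThreshold:
    def test_exact_power_law_atoms_give_r2_one(self):
        # atoms k_j = 2^j with counts 2^(9-j): log-log exactly linear, slope -1
        k = np.concatenate([[2.0**j] * (2 ** (9 - j)) for j in range(1, 9)])
        r2, slope = wgcna.scale_free_fit(k)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(-1.0, abs=1e-12)

    def test_degenerate_identical_connectivities(self):
        with pytest.raises(ValueError):
            wgcna.scale_free_fit(np.full(50, 3.0))

    def test_deterministic_on_fixed_seed_panel(self):
        m, _ = simulate_bulk_panel(n_genes=80, module_size=30, r_module=0.8, seed=6)
        S = wgcna.similarity(log_transform(m))
        b1, fit1, _ = wgcna.pick_soft_threshold(S, powers=tuple(range(1, 11)))
        b2, fit2, _ = wgcna.pick_soft_threshold(S, powers=tuple(range(1, 11)))
        assert b1 == b2
        pd.testing.assert_frame_equal(fit1, fit2)

    def test_returns_lowest_qualifying_power(self):
        m, _ = simulate_bulk_panel(n_genes=80, module_size=30, r_module=0.8, seed=6)
        S = wgcna.similarity(log_transform(m))
        beta, fit, reached = wgcna.pick_soft_threshold(S, powers=tuple(range(1, 11)), r2_cut=0.5)
        if reached:
            qualifying = fit[fit["r2"] >= 0.5]
            assert beta == qualifying["power"].iloc[0]


class TestTOM:
    def test_three_genes_hand_value(self):
        A = pd.DataFrame(np.full((3, 3), 0.5) - 0.5 * np.eye(3),
                         index=list("abc"), columns=list("abc"))
        T = wgcna.tom(A)
        assert T.iloc[0, 1] == pytest.approx(0.5)  # (0.25 + 0.5) / (1 + 1 - 0.5)

    def test_two_connected_genes(self):
        A = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"], columns=["a", "b"])
        T = wgcna.tom(A)
        assert T.iloc[0, 1] == pytest.approx(1.0)

    def test_empty_adjacency(self):
        A = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        T = wgcna.tom(A)
        off = T.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off == 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 13)
            raw = rng.random((n, n))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0.0)
            A = pd.DataFrame(a, index=[f"g{i}" for i in range(n)], columns=[f"g{i}" for i in range(n)])
            np.testing.assert_allclose(wgcna.tom(A).to_numpy(), tom_oracle(A), atol=1e-12)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(3)
        raw = rng.random((30, 30))
        S = pd.DataFrame((raw + raw.T) / 2, index=range(30), columns=range(30))
        T = wgcna.tom(wgcna.adjacency(S.clip(0, 1), 6))
        assert np.abs(T.to_numpy() - T.to_numpy().T).max() < 1e-10


def block_tom(sizes, within, between):
    n = sum(sizes)
    T = np.full((n, n), between)
    start = 0
    for s in sizes:
        T[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(T, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(T, index=ids, columns=ids)


class TestClusterCut:
    def test_two_blocks_top_merge_separates(self):
        T = block_tom([5, 5], 0.9, 0.1)
        Z = wgcna.cluster_genes(T)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_two_genes_single_merge(self):
        T = block_tom([1, 1], 0.9, 0.3)
        Z = wgcna.cluster_genes(T)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.7)

    def test_single_gene_rejected(self):
        T = block_tom([1], 0.9, 0.1)
        with pytest.raises(ValueError):
            wgcna.cluster_genes(T)

    def test_cut_two_planted_blocks(self):
        T = block_tom([60, 60], 0.9, 0.1)
        Z = wgcna.cluster_genes(T)
        mods = wgcna.cut_modules(Z, list(T.index), min_size=50)
        sizes = sorted(mods.labels.value_counts().to_dict().values())
        assert sizes == [60, 60]
        assert wgcna.UNASSIGNED not in set(mods.labels)

    def test_small_block_unassigned(self):
        T = block_tom([60, 40], 0.9, 0.1)
        Z = wgcna.cluster_genes(T)
        mods = wgcna.cut_modules(Z, list(T.index), min_size=50)
        counts = mods.labels.value_counts()
        assert counts[wgcna.UNASSIGNED] == 40
        assert len(mods.module_names) == 1

    def test_min_size_above_gene_count(self):
        T = block_tom([10, 10], 0.9, 0.1)
        Z = wgcna.cluster_genes(T)
        with pytest.warns(UserWarning):
            mods = wgcna.cut_modules(Z, list(T.index), min_size=50)
        assert set(mods.labels) == {wgcna.UNASSIGNED}


class TestEigengene:
    def test_rank_one_recovery(self):
        v = np.array([1.0, -1.0, 2.0, 0.0, -2.0])
        arr = np.vstack([5 + 2 * v, 2 + 0.5 * v, 5 + v])
        m = make_matrix(arr)
        eig = wgcna.module_eigengene(m, m.gene_ids)
        vz = (v - v.mean()) / v.std()
        corr = np.corrcoef(eig, vz)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)
        assert corr > 0  # positive orientation

    def test_orientation_with_opposed_members(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        arr = np.vstack([v, v, 10.0 - v])
        m = make_matrix(arr)
        eig = wgcna.module_eigengene(m, m.gene_ids)
        sub = m.values.to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        cors = [np.corrcoef(eig, row)[0, 1] for row in z]
        assert np.mean(cors) >= 0

    def test_unit_norm(self):
        m, _ = simulate_bulk_panel(n_genes=20, module_size=10, r_module=0.5, seed=0)
        eig = wgcna.module_eigengene(m, m.gene_ids[:10])
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_missing_member_rejected(self):
        m, _ = simulate_bulk_panel(n_genes=10, seed=0)
        with pytest.raises(ValueError, match="missing"):
            wgcna.module_eigengene(m, ["g0001", "nope"])


class TestMergeModules:
    def _modules_from(self, labels_dict):
        idx = pd.Index(list(labels_dict), name="gene_id")
        return wgcna.ModuleSet(labels=pd.Series([labels_dict[g] for g in idx], index=idx))

    def test_identical_eigengenes_merge(self):
        v = np.array([1.0, 5.0, 2.0, 4.0, 3.0, 6.0])
        rng = np.random.default_rng(0)
        arr = np.vstack([v + rng.normal(0, 0.01, 6) for _ in range(6)])
        m = make_matrix(arr)
        mods = self._modules_from({g: ("A" if i < 3 else "B") for i, g in enumerate(m.gene_ids)})
        merged = wgcna.merge_close_modules(m, mods, merge_cut=0.25)
        assert len(merged.module_names) == 1

    def test_orthogonal_modules_not_merged(self):
        v1 = 2.0 + np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        v2 = 2.0 + np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        rng = np.random.default_rng(1)
        arr = np.vstack([v1 + rng.normal(0, 0.01, 8) for _ in range(3)]
                        + [v2 + rng.normal(0, 0.01, 8) for _ in range(3)])
        m = make_matrix(arr)
        mods = self._modules_from({g: ("A" if i < 3 else "B") for i, g in enumerate(m.gene_ids)})
        merged = wgcna.merge_close_modules(m, mods, merge_cut=0.25)
        assert len(merged.module_names) == 2

    def test_bad_merge_cut(self):
        m, _ = simulate_bulk_panel(n_genes=10, seed=0)
        mods = self._modules_from({g: "A" for g in m.gene_ids})
        with pytest.raises(ValueError):
            wgcna.merge_close_modules(m, mods, merge_cut=1.5)


class TestTraitCorrelation:
    def test_perfect_correlation(self):
        trait = np.array([1.0, 1, 1, 0, 0, 0])
        eig = (trait - trait.mean())
        eig = eig / np.linalg.norm(eig)
        table = wgcna.module_trait_correlation(pd.DataFrame({"m": eig}), trait)
        assert table.loc["m", "r"] == pytest.approx(1.0)
        assert table.loc["m", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_trait(self):
        trait = np.array([1.0, 1, 0, 0])
        eig = np.array([1.0, -1, 1, -1])
        table = wgcna.module_trait_correlation(pd.DataFrame({"m": eig}), trait)
        assert table.loc["m", "r"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError):
            wgcna.module_trait_correlation(pd.DataFrame({"m": [1.0, 2, 3]}), np.ones(3))

    def test_planted_r_recovery(self):
        errs = []
        for seed in range(10):
            m, truth = simulate_bulk_panel(n_per_sex=6, n_genes=150, module_size=50,
                                           r_module=0.85, noise_sd=1.0, seed=seed)
            trait = np.array([1.0 if s.sex == "female" else 0.0 for s in m.samples])
            eig = wgcna.module_eigengene(log_transform(m), truth.planted_module["genes"])
            table = wgcna.module_trait_correlation(pd.DataFrame({"m": eig}), trait)
            errs.append(abs(abs(table.loc["m", "r"]) - 0.85))
        assert np.median(errs) <= 0.15


class TestSignificance:
    def test_gs_values(self):
        mods = wgcna.ModuleSet(labels=pd.Series({"g1": "A", "g2": "A"}))
        gs, ms = wgcna.significance(pd.Series({"g1": 0.01, "g2": 1.0}), mods)
        assert gs.loc["g1", "gs"] == pytest.approx(2.0)
        assert gs.loc["g2", "gs"] == pytest.approx(0.0)

    def test_ms_mean(self):
        mods = wgcna.ModuleSet(labels=pd.Series({"g1": "A", "g2": "A"}))
        _, ms = wgcna.significance(pd.Series({"g1": 0.1, "g2": 0.001}), mods)
        assert ms.loc["A", "ms"] == pytest.approx(2.0)

    def test_p_zero_capped(self):
        mods = wgcna.ModuleSet(labels=pd.Series({"g1": "A", "g2": "A"}))
        gs, _ = wgcna.significance(pd.Series({"g1": 0.0, "g2": 0.5}), mods)
        assert gs.loc["g1", "gs"] == wgcna.MAX_GS


class TestPipeline:
    def test_planted_module_recovery(self):
        m, truth = simulate_bulk_panel(n_per_sex=6, n_genes=300, module_size=60,
                                       r_module=0.85, noise_sd=1.0, seed=1)
        trait = np.array([1.0 if s.sex == "female" else 0.0 for s in m.samples])
        mods, fit, beta = wgcna.run_wgcna(log_transform(m), trait=trait,
                                          min_size=50, cut_height_q=0.95)
        assert mods.module_names
        top = mods.trait_correlation["r"].abs().idxmax()
        planted = set(truth.planted_module["genes"])
        members = set(mods.members(top))
        assert len(members & planted) / len(planted) >= 0.8
        assert abs(mods.trait_correlation.loc[top, "r"]) >= 0.8

    def test_permuted_trait_destroys_correlation(self):
        m, _ = simulate_bulk_panel(n_per_sex=6, n_genes=200, module_size=60,
                                   r_module=0.85, noise_sd=1.0, seed=2)
        trait = np.array([1.0 if s.sex == "female" else 0.0 for s in m.samples])
        mods, _, _ = wgcna.run_wgcna(log_transform(m), trait=trait,
                                     min_size=50, cut_height_q=0.95)
        observed = mods.trait_correlation["r"].abs().max()
        rng = np.random.default_rng(0)
        null = []
        for _ in range(50):
            perm = rng.permutation(trait)
            null.append(wgcna.module_trait_correlation(mods.eigengenes, perm)["r"].abs().max())
        assert observed > np.quantile(null, 0.95)
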