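"""Co-methylation network: bicor, TOM, modules, eigenvectors, trait stats."""

import numpy as np
import pandas as pd
import pytest

from salmeth.io import GenomicInterval, MethylationMatrix
from salmeth.network import (
    WindowMatrix,
    adjacency_and_tom,
    bicor,
    bicor_matrix,
    build_network,
    detect_modules,
    mm_gs_comparison,
    module_dmr_enrichment,
    module_eigenvectors,
    summarize_windows,
    trait_association,
)


def _bicor_oracle(x, y):
    """Direct double-loop evaluation of the published bicor formula."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - np.mean(v)
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    num = sum(ai * bi for ai, bi in zip(a, b))
    return num / (np.sqrt(sum(ai * ai for ai in a)) * np.sqrt(sum(bi * bi for bi in b)))


def _tom_oracle(a):
    """Triple-loop topological overlap from an adjacency with zero diagonal."""
    n = a.shape[0]
    tom = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestSummarizeWindows:
    def _matrix(self, pos, meth, total):
        n = len(pos)
        return MethylationMatrix(
            np.array(["chr1"] * n, dtype=object), np.asarray(pos),
            [f"s{i}" for i in range(np.asarray(meth).shape[1])],
            np.asarray(meth, float), np.asarray(total, float),
        )

    def test_pooled_ratio(self):
        meth = [[4, 0], [6, 0], [10, 10]]
        total = [[10, 10], [10, 10], [10, 10]]
        m = self._matrix([110, 150, 190], meth, total)
        wm = summarize_windows(m, min_var=0.0)
        assert wm.n_windows == 1
        assert wm.values[0, 0] == pytest.approx(20 / 30)
        assert wm.n_cpg[0] == 3

    def test_min_cpg_filter(self):
        m = self._matrix([110, 150], [[1, 9], [2, 8]], [[10, 10], [10, 10]])
        assert summarize_windows(m).n_windows == 0

    def test_variance_filter(self):
        # constant across samples -> dropped even with 3 CpGs
        m = self._matrix([110, 150, 190], np.full((3, 4), 5.0), np.full((3, 4), 10.0))
        assert summarize_windows(m).n_windows == 0


class TestBicor:
    def test_self_and_antisymmetry(self):
        x = np.array([0.1, 0.5, 0.9, 0.3, 0.2, 0.8])
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_published_formula_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            assert bicor(x, y) == pytest.approx(_bicor_oracle(x, y), abs=1e-10)

    def test_zero_mad_pearson_fallback(self):
        # x has MAD 0 (majority identical): falls back to mean-centering
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0])
        y = np.array([0.2, 0.1, 0.4, 0.3, 0.9])
        r = bicor(x, y)
        assert np.isfinite(r) and -1 <= r <= 1

    def test_matrix_agrees_with_pairs(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=(6, 12))
        c = bicor_matrix(vals)
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert c[i, j] == pytest.approx(
                        _bicor_oracle(vals[i], vals[j]), abs=1e-10
                    )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bicor(np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            bicor_matrix(np.ones((3, 2)))


class TestTom:
    def test_two_node_collapse(self):
        c = np.array([[1.0, 0.6], [0.6, 1.0]])
        a, tom = adjacency_and_tom(c, power=3)
        assert tom[0, 1] == pytest.approx(a[0, 1]) == pytest.approx(0.6**3)

    def test_identical_columns_full_overlap(self):
        c = np.ones((4, 4))
        _, tom = adjacency_and_tom(c, power=18)
        assert np.allclose(tom, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(5, 20))
        c = np.corrcoef(x)
        a, tom = adjacency_and_tom(c, power=6)
        assert np.allclose(tom, _tom_oracle(a), atol=1e-12)

    def test_range_symmetry_diagonal(self):
        rng = np.random.default_rng(4)
        c = np.corrcoef(rng.normal(size=(15, 10)))
        _, tom = adjacency_and_tom(c)
        assert ((tom >= 0) & (tom <= 1)).all()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_bad_power(self):
        with pytest.raises(ValueError):
            adjacency_and_tom(np.eye(2), power=0)


def _planted_values(rng, n_mod=3, size=30, noise=50, n_samp=16, load=np.sqrt(0.9)):
    blocks, labels = [], []
    for m in range(n_mod):
        z = rng.normal(size=n_samp)
        sig = load * z[None, :] + np.sqrt(1 - load**2) * rng.normal(size=(size, n_samp))
        blocks.append(sig)
        labels += [m + 1] * size
    blocks.append(rng.normal(size=(noise, n_samp)))
    labels += [0] * noise
    return np.vstack(blocks), np.array(labels)


class TestModules:
    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        vals, truth = _planted_values(rng)
        c = bicor_matrix(vals)
        _, tom = adjacency_and_tom(c, power=18)
        labels = detect_modules(1 - tom, values=vals)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_all_noise_unassigned(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(40, 16))
        c = bicor_matrix(vals)
        _, tom = adjacency_and_tom(c, power=18)
        labels = detect_modules(1 - tom, values=vals)
        assert (labels == 0).all()

    def test_small_cluster_below_floor_unassigned(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=16)
        vals = 0.95 * z[None, :] + 0.05 * rng.normal(size=(5, 16))
        c = bicor_matrix(vals)
        _, tom = adjacency_and_tom(c, power=18)
        labels = detect_modules(1 - tom, values=vals, min_module_size=10)
        assert (labels == 0).all()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(np.zeros((3, 4)))


class TestEigenvectors:
    def _wm(self, vals):
        n = vals.shape[0]
        wins = [GenomicInterval("chr1", i * 100, (i + 1) * 100, f"w{i}")
                for i in range(n)]
        return WindowMatrix(wins, vals, np.full(n, 3),
                            [f"s{i}" for i in range(vals.shape[1])])

    def test_rank_one_module(self):
        base = np.linspace(0.1, 0.9, 8)
        vals = np.tile(base, (5, 1))
        modset = module_eigenvectors(self._wm(vals), np.ones(5, dtype=int))
        v = modset.eigenvectors[1]
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert abs(np.corrcoef(v, base)[0, 1]) == pytest.approx(1.0)
        assert np.allclose(modset.mm, 1.0)
        # sign convention: correlates positively with module mean methylation
        assert np.corrcoef(v, vals.mean(axis=0))[0, 1] > 0

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(size=(10, 12))
        modset = module_eigenvectors(self._wm(vals), np.ones(10, dtype=int))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1,
                                                                 keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)
        top = evecs[:, np.argmax(evals)]
        assert abs(abs(modset.eigenvectors[1] @ top) - 1) < 1e-8

    def test_first_axis_beats_any_single_window(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(size=(6, 10))
        modset = module_eigenvectors(self._wm(vals), np.ones(6, dtype=int))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1,
                                                                 keepdims=True)
        v = modset.eigenvectors[1]
        var_v = np.sum((z @ v) ** 2)
        for row in z:
            assert var_v >= np.sum((z @ (row / np.linalg.norm(row))) ** 2) - 1e-9


class TestTraitAssociation:
    def _modset_with_vec(self, v):
        from salmeth.network import ModuleSet

        labels = np.ones(3, dtype=int)
        return ModuleSet(labels, {1: v / np.linalg.norm(v)}, np.ones(3),
                         [f"s{i}" for i in range(len(v))])

    def test_printed_p_convention(self):
        """r = 0.69 at n = 16 gives a two-sided t p that rounds to 0.003."""
        from salmeth.network import _cor_t_pvalue

        assert round(_cor_t_pvalue(0.69, 16), 3) == 0.003

    def test_zero_and_perfect_correlation(self):
        from salmeth.network import _cor_t_pvalue

        assert _cor_t_pvalue(0.0, 16) == pytest.approx(1.0)
        assert _cor_t_pvalue(1.0, 16) > 0  # smallest representable, not 0

    def test_trait_equal_to_eigenvector(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=16)
        modset = self._modset_with_vec(v)
        phen = pd.DataFrame({"trait": v}, index=modset.samples)
        mt, _ = trait_association(modset, phen)
        assert mt.iloc[0]["r"] == pytest.approx(1.0)
        assert mt.iloc[0]["p"] > 0

    def test_constant_trait_rejected(self):
        modset = self._modset_with_vec(np.arange(16.0))
        phen = pd.DataFrame({"trait": np.ones(16)}, index=modset.samples)
        with pytest.raises(ValueError, match="constant"):
            trait_association(modset, phen)


class TestModuleDmrEnrichment:
    def test_module_equals_background(self):
        flags = np.zeros(30, dtype=bool)
        flags[:10] = True
        res = module_dmr_enrichment(np.arange(30), flags, n_perm=50, seed=1)
        assert res.observed == 10 and res.p_emp == 1.0

    def test_no_dmrs(self):
        res = module_dmr_enrichment(np.arange(5), np.zeros(50, dtype=bool),
                                    n_perm=50, seed=2)
        assert res.observed == 0 and res.p_emp == 1.0

    def test_planted_enrichment_minimal_p(self):
        flags = np.zeros(400, dtype=bool)
        flags[:20] = True  # module windows all flagged; 5% elsewhere
        flags[380:] = True
        res = module_dmr_enrichment(np.arange(20), flags, n_perm=1000, seed=3)
        assert res.p_emp == pytest.approx(1 / 1001)

    def test_oversized_module_rejected(self):
        with pytest.raises(ValueError):
            module_dmr_enrichment(np.arange(5), np.zeros(3, dtype=bool))


class TestMmGs:
    def test_identical_strata(self):
        vals = np.tile([0.5, 0.6, 0.7, 0.8], 2)
        flags = np.array([True] * 4 + [False] * 4)
        out = mm_gs_comparison(vals, vals, flags)
        assert np.allclose(out["t"], 0) and np.allclose(out["p"], 1)

    def test_matches_welch_formula(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 0.05, 20)
        b = rng.normal(0.6, 0.05, 20)
        vals = np.concatenate([a, b])
        flags = np.array([True] * 20 + [False] * 20)
        out = mm_gs_comparison(vals, vals, flags).iloc[0]
        va, vb = a.var(ddof=1) / 20, b.var(ddof=1) / 20
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 19 + vb**2 / 19)
        assert out["t"] == pytest.approx(t, abs=1e-10)
        assert out["df"] == pytest.approx(df, abs=1e-10)
        assert out["df"] != int(out["df"])  # Welch df is fractional

    def test_tiny_stratum_untestable(self):
        vals = np.arange(5.0)
        flags = np.array([True, False, False, False, False])
        out = mm_gs_comparison(vals, vals, flags)
        assert not out["testable"].any()


def _wm_from(vals, split_chrom_at=None):
    n = vals.shape[0]
    wins = []
    for i in range(n):
        chrom = "chr1" if split_chrom_at is None or i < split_chrom_at else "chr2"
        wins.append(GenomicInterval(chrom, i * 100, (i + 1) * 100, f"w{i}"))
    return WindowMatrix(wins, vals, np.full(n, 3),
                        [f"s{i}" for i in range(vals.shape[1])])


def test_build_network_blockwise_matches_single_block():
    """Chromosome-local modules come out the same whether the network is
    built in one block or chromosome-contiguous blocks."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(12)
    vals, truth = _planted_values(rng, n_mod=2, size=20, noise=20)
    # module 1 + half the noise on chr1, module 2 + the rest on chr2
    order = np.concatenate([np.arange(0, 20), np.arange(40, 50),
                            np.arange(20, 40), np.arange(50, 60)])
    wm = _wm_from(vals[order], split_chrom_at=30)
    t = truth[order]
    full = build_network(wm, max_block=10_000)
    blocked = build_network(wm, max_block=30)
    assert adjusted_rand_score(t, full.labels) >= 0.8
    assert adjusted_rand_score(t, blocked.labels) >= 0.8


def test_cross_block_module_halves_are_merged():
    """A module split across two blocks (each half above the size floor)
    is reunified by eigenvector-correlation merging."""
    rng = np.random.default_rng(13)
    vals, truth = _planted_values(rng, n_mod=1, size=24, noise=0)
    # half the module on each chromosome -> separate blocks
    wm = _wm_from(vals, split_chrom_at=12)
    modset = build_network(wm, max_block=12, min_module_size=10)
    assert len(modset.module_ids()) == 1
    assert (modset.labels == modset.labels[0]).all()
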