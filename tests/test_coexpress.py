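"""Co-expression chain: each operation against a brute-force oracle, plus
module detection/merging behaviour on planted block structure."""

import math

import numpy as np
import pandas as pd
import pytest

from calnc import coexpress as cx
from calnc.types import CalncError


def random_expr(n_genes, n_samples, seed=0, index=None):
    rng = np.random.default_rng(seed)
    idx = index or [f"g{i:03d}" for i in range(n_genes)]
    return pd.DataFrame(rng.normal(5, 1, (n_genes, n_samples)), index=idx,
                        columns=[f"s{j}" for j in range(n_samples)])


def block_expr(sizes, loading, n_noise, n_samples=54, seed=0):
    """Planted-block log-expression: members load on a block factor."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for bi, size in enumerate(sizes):
        z = rng.normal(size=n_samples)
        for _ in range(size):
            e = rng.normal(size=n_samples)
            rows.append(loading * z + math.sqrt(1 - loading**2) * e)
            labels.append(f"B{bi}")
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append("noise")
    idx = [f"g{i:04d}" for i in range(len(rows))]
    df = pd.DataFrame(5.0 + np.array(rows), index=idx,
                      columns=[f"s{j}" for j in range(n_samples)])
    return df, pd.Series(labels, index=idx)


class TestPrefilterMad:
    def test_prefilter_rules(self):
        vals = pd.DataFrame({
            "all_low": np.full(54, 0.5),
            "ten_high": np.r_[np.full(10, 2.0), np.full(44, 0.5)],
            "high": np.full(54, 5.0),
        }).T
        out = cx.prefilter(vals, expr_cutoff=1.0, sample_frac=0.9)
        assert "all_low" not in out.index       # below 1 FPKM everywhere
        assert "ten_high" in out.index          # >= 1 FPKM in 18.5% of samples
        out2 = cx.prefilter(vals, expr_cutoff=1.0, sample_frac=1.0)
        assert set(out2.index) == {"ten_high", "high"}

    def test_prefilter_empty_errors(self):
        vals = pd.DataFrame({"low": np.full(10, 0.01)}).T
        with pytest.raises(CalncError, match="lower"):
            cx.prefilter(vals)

    def test_mad_prefers_varying_row(self):
        vals = pd.DataFrame({"const": np.full(10, 5.0),
                             "vary": np.r_[np.full(5, 1.0), np.full(5, 9.0)]}).T
        out = cx.mad_topn(vals, 1)
        assert list(out.index) == ["vary"]

    def test_mad_n_at_least_rows_is_identity(self):
        vals = random_expr(5, 10)
        assert cx.mad_topn(vals, 5).equals(vals)
        assert cx.mad_topn(vals, 99).equals(vals)

    def test_mad_matches_brute_force_ranking(self):
        vals = random_expr(100, 10, seed=3)
        out = cx.mad_topn(vals, 30)
        med = vals.sub(vals.median(axis=1), axis=0).abs().median(axis=1)
        want = set(sorted(vals.index, key=lambda g: (-med[g], g))[:30])
        assert set(out.index) == want


class TestAdjacencyTom:
    @pytest.mark.parametrize("cor,beta,want", [
        (-0.5, 2, 0.25), (0.7, 1, 0.7), (0.0, 5, 0.0),
    ])
    def test_unsigned_adjacency(self, cor, beta, want):
        c = np.array([[1.0, cor], [cor, 1.0]])
        a = cx.adjacency(c, beta)
        assert a[0, 1] == pytest.approx(want)
        assert a[0, 0] == 1.0

    def test_signed_adjacency(self):
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert cx.adjacency(c, 2, "signed")[0, 1] == 0.0

    def test_tom_identity_adjacency(self):
        assert np.allclose(cx.tom_similarity(np.eye(4)), np.eye(4))

    def test_tom_complete_graph(self):
        a = np.ones((3, 3))
        assert np.allclose(cx.tom_similarity(a), 1.0)

    def test_tom_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(CalncError):
            cx.tom_similarity(a)

    def test_tom_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        n = 20
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                want = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(want, abs=1e-12)

    def test_tom_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = cx.tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()


class TestSoftThreshold:
    def test_fallback_to_beta_max(self):
        # featureless data never reaches the scale-free fit
        vals = random_expr(30, 20, seed=5)
        beta, fit = cx.pick_soft_threshold(vals, r2_cutoff=0.999, beta_max=6)
        assert beta == 6
        assert len(fit) == 6

    def test_fit_r2_matches_rebinning_oracle(self):
        """R^2 per beta equals an independent histogram + regression."""
        vals, _ = block_expr((20, 20), 0.95, 0, n_samples=30, seed=8)
        cor = cx.correlation_matrix(vals).to_numpy()
        from scipy.stats import linregress
        for beta in (2, 6, 12):
            a = cx.adjacency(cor, beta)
            k = a.sum(0) - 1
            got_r2, got_slope = cx.scale_free_fit(k)
            kk = k[k > 0]
            edges = np.linspace(kk.min(), kk.max() + 1e-12, 11)
            which = np.clip(np.digitize(kk, edges) - 1, 0, 9)
            xs, ys = [], []
            for b in range(10):
                m = which == b
                if m.any():
                    xs.append(np.log10(kk[m].mean()))
                    ys.append(np.log10(m.mean()))
            res = linregress(xs, ys)
            assert got_r2 == pytest.approx(res.rvalue**2, abs=1e-12)
            assert got_slope == pytest.approx(res.slope, abs=1e-12)

    def test_constant_gene_errors(self):
        vals = random_expr(10, 10, seed=1)
        vals.iloc[0] = 3.0
        with pytest.raises(CalncError, match="g000"):
            cx.pick_soft_threshold(vals)


class TestModules:
    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        vals, truth = block_expr((50, 50), 0.95, 20, seed=4)
        cor = cx.correlation_matrix(vals).to_numpy()
        tom = cx.tom_similarity(cx.adjacency(cor, 6))
        labels = cx.detect_modules(tom, list(vals.index), min_module_size=30)
        blocks = truth.index[truth != "noise"]
        assert adjusted_rand_score(truth[blocks], labels[blocks]) == 1.0
        assert set(labels[blocks]) == {"turquoise", "blue"}

    def test_small_block_goes_grey(self):
        vals, truth = block_expr((40, 10), 0.95, 0, seed=6)
        cor = cx.correlation_matrix(vals).to_numpy()
        tom = cx.tom_similarity(cx.adjacency(cor, 6))
        labels = cx.detect_modules(tom, list(vals.index), min_module_size=30)
        small = truth.index[truth == "B1"]
        assert (labels[small] == "grey").all()

    def test_pure_noise_all_grey(self):
        vals, _ = block_expr((), 0.9, 60, seed=7)
        cor = cx.correlation_matrix(vals).to_numpy()
        tom = cx.tom_similarity(cx.adjacency(cor, 6))
        labels = cx.detect_modules(tom, list(vals.index), min_module_size=30)
        assert (labels == "grey").all()

    def test_fewer_genes_than_min_size_all_grey(self):
        labels = cx.detect_modules(np.eye(5), list("abcde"), min_module_size=30)
        assert (labels == "grey").all()


class TestEigengene:
    def test_identical_rows_variance_one(self):
        row = np.sin(np.linspace(0, 6, 20)) + 2
        vals = pd.DataFrame([row] * 5, index=list("abcde"))
        eig, ve = cx.module_eigengene(vals, list("abcde"))
        assert ve == pytest.approx(1.0)
        std = (row - row.mean()) / row.std()
        assert np.allclose(np.abs(eig), np.abs(std / np.linalg.norm(std)))
        assert np.corrcoef(eig, row)[0, 1] > 0    # sign follows mean profile

    def test_singleton_module(self):
        vals = random_expr(3, 12, seed=9)
        eig, ve = cx.module_eigengene(vals, ["g000"])
        assert ve == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_variance_explained_matches_eigendecomposition(self):
        vals = random_expr(30, 54, seed=10)
        _, ve = cx.module_eigengene(vals, list(vals.index))
        x = vals.to_numpy()
        x = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        evals = np.linalg.eigvalsh(x @ x.T)
        assert ve == pytest.approx(evals[-1] / evals.sum(), rel=1e-10)

    def test_sample_permutation_invariance(self):
        vals = random_expr(10, 20, seed=11)
        eig, ve = cx.module_eigengene(vals, list(vals.index))
        perm = np.random.default_rng(0).permutation(20)
        eig_p, ve_p = cx.module_eigengene(vals.iloc[:, perm], list(vals.index))
        assert ve_p == pytest.approx(ve)
        assert np.allclose(np.abs(eig_p), np.abs(eig[perm]))


class TestMergeKme:
    def _labelled_blocks(self, cors, seed=12, size=10, n_samples=40):
        """Modules built from latent factors with chosen pairwise cor."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n_samples)
        rows, labels = [], []
        for mi, c in enumerate(cors):
            z = c * base + math.sqrt(1 - c**2) * rng.normal(size=n_samples)
            for _ in range(size):
                rows.append(z + 0.05 * rng.normal(size=n_samples))
                labels.append(cx.MODULE_COLORS[mi])
        idx = [f"g{i:03d}" for i in range(len(rows))]
        return (pd.DataFrame(rows, index=idx), pd.Series(labels, index=idx))

    def test_highly_correlated_modules_merge(self):
        vals, labels = self._labelled_blocks([1.0, 0.99])
        merged = cx.merge_modules(vals, labels, merge_cut_height=0.25)
        assert len(set(merged)) == 1

    def test_distinct_modules_not_merged(self):
        vals, labels = self._labelled_blocks([1.0, 0.0])
        merged = cx.merge_modules(vals, labels, merge_cut_height=0.25)
        assert len(set(merged)) == 2

    def test_three_way_merge_iterates_to_one(self):
        vals, labels = self._labelled_blocks([1.0, 0.98, 0.97])
        merged = cx.merge_modules(vals, labels, merge_cut_height=0.25)
        assert len(set(merged)) == 1

    def test_kme_extremes(self):
        vals = random_expr(5, 30, seed=13)
        eig, _ = cx.module_eigengene(vals, list(vals.index))
        vals.loc["clone"] = 5 + eig
        k = cx.kme(vals, eig)
        assert k["clone"] == pytest.approx(1.0)
        retained = cx.kme_filter(vals, list(vals.index), eig, kme_cutoff=0.999)
        assert "clone" in retained

    def test_kme_orthogonal_dropped(self):
        rng = np.random.default_rng(14)
        eig = rng.normal(size=30)
        eig /= np.linalg.norm(eig)
        vals = pd.DataFrame({"ortho": rng.normal(size=30)}).T
        assert cx.kme_filter(vals, ["ortho"], eig, kme_cutoff=0.9) == []


class TestTraitEnrichExport:
    def test_trait_correlation_extremes(self):
        ind = np.r_[np.ones(10), np.zeros(10)]
        eig = (ind - ind.mean())
        eig /= np.linalg.norm(eig)
        r, p = cx.module_trait_correlation(eig, ind)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(CalncError):
            cx.module_trait_correlation(eig, np.ones(20))

    def test_trait_p_formula(self):
        rng = np.random.default_rng(15)
        eig = rng.normal(size=54)
        ind = np.r_[np.ones(27), np.zeros(27)]
        r, p = cx.module_trait_correlation(eig, ind)
        from scipy.stats import pearsonr
        want = pearsonr(eig, ind)
        assert r == pytest.approx(want.statistic, rel=1e-12)
        assert p == pytest.approx(want.pvalue, rel=1e-9)

    def test_hypergeometric_tail_example(self):
        """N=20, K=4, n=5, k=3: p = [C(4,3)C(16,2) + C(4,4)C(16,1)]/C(20,5)."""
        universe = [f"g{i}" for i in range(20)]
        term_genes = universe[:4]
        module = universe[:3] + universe[10:12]
        res = cx.enrich_hypergeometric(module, {g: ["T"] for g in term_genes}, universe)
        want = (math.comb(4, 3) * math.comb(16, 2)
                + math.comb(4, 4) * math.comb(16, 1)) / math.comb(20, 5)
        assert res.p.iloc[0] == pytest.approx(want, rel=1e-12)

    def test_enrichment_k0_and_extreme(self):
        universe = [f"g{i}" for i in range(20)]
        res = cx.enrich_hypergeometric(universe[:5],
                                       {g: ["T"] for g in universe[10:14]}, universe)
        assert res.p.iloc[0] == pytest.approx(1.0)    # k = 0
        res2 = cx.enrich_hypergeometric(universe[:4],
                                        {g: ["T"] for g in universe[:4]}, universe)
        assert res2.p.iloc[0] == pytest.approx(1 / math.comb(20, 4), rel=1e-9)

    def test_empty_term_map(self):
        assert cx.enrich_hypergeometric(["a"], {}, ["a", "b"]).empty

    def test_export_threshold_bounds(self):
        w = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 1.0]])
        ids = ["a", "b", "c"]
        edges, nodes = cx.export_network(w, ids, 1.1)
        assert edges.empty and nodes.empty
        edges, _ = cx.export_network(w, ids, 0.0)
        assert len(edges) == 3    # complete graph minus self-loops

    def test_export_respects_block_structure(self):
        w = np.full((4, 4), 0.05)
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        np.fill_diagonal(w, 1.0)
        edges, nodes = cx.export_network(w, list("abcd"), 0.5)
        got = {tuple(sorted(e)) for e in zip(edges.source, edges.target)}
        assert got == {("a", "b"), ("c", "d")}
        assert set(nodes.gene) == set("abcd")
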