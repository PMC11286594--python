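import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

import graftaxis as ga
from graftaxis.errors import (
    ConstantRowError,
    EmptyNetworkError,
    KExceedsPointsError,
    NoReferenceGenesError,
    PerplexityTooLargeError,
    TargetExceedsGenesError,
)


def _expr(rows, index=None, columns=None, **kw):
    rows = np.asarray(rows, dtype=float)
    index = index or [f"g{i+1}" for i in range(rows.shape[0])]
    columns = columns or [f"s{j+1}" for j in range(rows.shape[1])]
    return ga.ExpressionMatrix(pd.DataFrame(rows, index=index, columns=columns), **kw)


class TestSizeFactorNormalize:
    def test_median_of_ratios_worked_example(self):
        # samples (2,4) and (8,16): geometric means (4,8), both ratio medians
        # give size factors (0.5, 2); both columns normalize to (4,8)
        counts = _expr([[2, 8], [4, 16]], normalized=False)
        out = ga.size_factor_normalize(counts)
        assert np.allclose(out.data.to_numpy(), [[4, 4], [8, 8]])
        assert out.normalized

    def test_identical_samples_unchanged(self):
        counts = _expr([[3, 3, 3], [7, 7, 7]], normalized=False)
        out = ga.size_factor_normalize(counts)
        assert out.data.to_numpy() == pytest.approx(counts.data.to_numpy())

    def test_zero_containing_gene_excluded_from_reference_but_rescaled(self):
        counts = _expr([[2, 8], [4, 16], [0, 10]], normalized=False)
        out = ga.size_factor_normalize(counts)
        # factors still (0.5, 2) from the two zero-free genes
        assert out.data.loc["g3"].to_numpy() == pytest.approx([0.0, 5.0])
        assert out.data.loc["g1"].to_numpy() == pytest.approx([4.0, 4.0])

    def test_no_reference_genes_raises(self):
        counts = _expr([[0, 5], [5, 0]], normalized=False)
        with pytest.raises(NoReferenceGenesError):
            ga.size_factor_normalize(counts)


class TestSelectVariableGenes:
    def test_cv_ranking_worked_example(self, tiny_expression):
        # CVs: g1=0, g2=0.5, g3=1.0 (sample sd / mean)
        genes, threshold = ga.select_variable_genes(tiny_expression, 2)
        assert genes == ["g3", "g2"]
        assert threshold == pytest.approx(0.5)

    def test_constant_gene_never_beats_varying(self, tiny_expression):
        genes, _ = ga.select_variable_genes(tiny_expression, 2)
        assert "g1" not in genes

    def test_ties_broken_lexicographically(self):
        expr = _expr([[1, 2, 3], [1, 2, 3]], index=["gb", "ga"])
        genes, _ = ga.select_variable_genes(expr, 1)
        assert genes == ["ga"]

    def test_target_exceeds_genes(self, tiny_expression):
        with pytest.raises(TargetExceedsGenesError):
            ga.select_variable_genes(tiny_expression, 99)

    def test_invariant_to_sample_order(self, rng):
        data = pd.DataFrame(rng.gamma(2, 30, (20, 6)),
                            index=[f"g{i:02d}" for i in range(20)],
                            columns=[f"s{j}" for j in range(6)])
        expr = ga.ExpressionMatrix(data)
        shuffled = ga.ExpressionMatrix(data[["s3", "s0", "s5", "s1", "s4", "s2"]])
        assert ga.select_variable_genes(expr, 7) == ga.select_variable_genes(shuffled, 7)


class TestZscore:
    def test_worked_example(self):
        z = ga.zscore_genes(_expr([[1, 2, 3], [4, 4, 5]]))
        assert z.data.loc["g1"].to_numpy() == pytest.approx([-1, 0, 1])

    def test_idempotent_to_tolerance(self, rng):
        expr = _expr(rng.gamma(2, 30, (10, 8)))
        z1 = ga.zscore_genes(expr)
        z2 = ga.zscore_genes(ga.ExpressionMatrix(z1.data, zscored=True))
        assert np.abs(z2.data.to_numpy() - z1.data.to_numpy()).max() < 1e-10

    def test_constant_row_raises(self):
        with pytest.raises(ConstantRowError):
            ga.zscore_genes(_expr([[5, 5, 5], [1, 2, 3]]))


def _two_module_z(n_per=60, n_samples=12, loading=0.95, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((2, n_samples))
    rows, labels = [], []
    for m in range(2):
        rows.append(loading * f[m] + noise * rng.standard_normal((n_per, n_samples)))
        labels += [m] * n_per
    data = pd.DataFrame(np.vstack(rows),
                        index=[f"g{i:03d}" for i in range(2 * n_per)],
                        columns=[f"s{j}" for j in range(n_samples)])
    z = ga.zscore_genes(ga.ExpressionMatrix(np.exp(data), normalized=True))
    return z, np.array(labels)


class TestEmbedGenes:
    def test_shape_finite_and_deterministic(self):
        z, _ = _two_module_z()
        emb1 = ga.embed_genes(z, perplexity=10, seed=3)
        emb2 = ga.embed_genes(z, perplexity=10, seed=3)
        assert emb1.shape == (120, 2)
        assert np.isfinite(emb1.to_numpy()).all()
        assert (emb1.to_numpy() == emb2.to_numpy()).all()

    def test_planted_modules_separate_in_embedding(self):
        z, labels = _two_module_z()
        emb = ga.embed_genes(z, perplexity=10, seed=0)
        assert silhouette_score(emb.to_numpy(), labels) > 0

    def test_perplexity_too_large(self):
        z, _ = _two_module_z(n_per=10)
        with pytest.raises(PerplexityTooLargeError):
            ga.embed_genes(z, perplexity=30)


def _blobs(centers, n_per=20, spread=0.05, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([c + spread * rng.standard_normal((n_per, 2)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    idx = [f"g{i:03d}" for i in range(len(pts))]
    return pd.DataFrame(pts, index=idx, columns=["tsne1", "tsne2"]), labels


class TestClusterGenes:
    def test_k1_single_label(self):
        emb, _ = _blobs([(0, 0), (10, 10)])
        labels = ga.cluster_genes(emb, k=1)
        assert set(labels) == {1}

    def test_two_blobs_recovered_exactly(self):
        emb, truth = _blobs([(0, 0), (10, 10)])
        labels = ga.cluster_genes(emb, k=2, seed=1)
        # same partition irrespective of numbering
        mapping = {lab: truth[labels.to_numpy() == lab][0] for lab in (1, 2)}
        assert all(mapping[lab] == t for lab, t in zip(labels, truth))

    def test_canonical_numbering_largest_first(self):
        emb, _ = _blobs([(0, 0)], n_per=30)
        emb2, _ = _blobs([(10, 10)], n_per=10, seed=1)
        emb2.index = [f"h{i}" for i in range(10)]
        both = pd.concat([emb, emb2])
        labels = ga.cluster_genes(both, k=2, seed=0)
        assert (labels.iloc[:30] == 1).all() and (labels.iloc[30:] == 2).all()

    def test_k_exceeds_points(self):
        emb, _ = _blobs([(0, 0)], n_per=5)
        with pytest.raises(KExceedsPointsError):
            ga.cluster_genes(emb, k=6)


class TestNetworkActivity:
    def test_mean_of_members(self):
        z = ga.ExpressionMatrix(
            pd.DataFrame([[1, -1, 0], [-1, 1, 0], [2, 0, -2]],
                         index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"]),
            zscored=True)
        labels = pd.Series([1, 1, 2], index=["g1", "g2", "g3"])
        act = ga.network_activity(z, labels)
        assert act.loc[1].to_numpy() == pytest.approx([0, 0, 0])
        assert act.loc[2].to_numpy() == pytest.approx([2, 0, -2])  # single-gene row

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.standard_normal((6, 4)),
                            index=list("abcdef"), columns=list("wxyz"))
        z = ga.ExpressionMatrix(data, zscored=True)
        labels = pd.Series([1, 2, 1, 2, 1, 2], index=list("abcdef"))
        act1 = ga.network_activity(z, labels)
        perm = list("fedcba")
        z2 = ga.ExpressionMatrix(data.loc[perm], zscored=True)
        act2 = ga.network_activity(z2, labels.loc[perm])
        assert np.allclose(act1.to_numpy(), act2.to_numpy())

    def test_merging_networks_gives_size_weighted_mean(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.standard_normal((5, 4)),
                            index=list("abcde"), columns=list("wxyz"))
        z = ga.ExpressionMatrix(data, zscored=True)
        split = pd.Series([1, 1, 1, 2, 2], index=list("abcde"))
        merged = pd.Series([1, 1, 1, 1, 1], index=list("abcde"))
        act_split = ga.network_activity(z, split)
        act_merged = ga.network_activity(z, merged)
        weighted = (3 * act_split.loc[1] + 2 * act_split.loc[2]) / 5
        assert np.allclose(act_merged.loc[1], weighted)

    def test_uncovered_gene_raises(self):
        z = ga.ExpressionMatrix(
            pd.DataFrame(np.eye(3), index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"]),
            zscored=True)
        with pytest.raises(EmptyNetworkError):
            ga.network_activity(z, pd.Series([1, 2], index=["g1", "g2"]))


class TestChooseK:
    def test_singleton_grid_returned_as_is(self):
        emb, _ = _blobs([(0, 0), (5, 5)])
        assert ga.choose_k(emb, [2]) == 2

    def test_three_blobs_silhouette_maximum(self):
        emb, _ = _blobs([(0, 0), (10, 0), (5, 9)], n_per=25)
        assert ga.choose_k(emb, [2, 3, 4, 5, 6], seed=0) == 3


class TestFullChain:
    def test_call_gene_networks_smoke(self, small_config):
        bundle, truth = ga.generate_cohort(small_config, seed=0)
        res = ga.call_gene_networks(bundle.expression, target_count=240,
                                    k=4, perplexity=15, seed=0)
        assert res.k == 4
        assert len(res.selected_genes) == 240
        assert sorted(set(res.labels)) == [1, 2, 3, 4]
        assert res.activity.shape == (4, small_config.n_samples)
        assert list(res.activity.columns) == bundle.sample_ids
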