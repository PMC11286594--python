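"""Coregulated gene-network calling.

The procedure mirrors the embedding-based coregulation analysis used for
bulk transplant transcriptomes: size-factor normalization (median of
ratios), selection of highly variable genes by coefficient of variation,
gene-wise z-scoring across samples, 2-D t-SNE of the genes (samples are the
feature dimensions), and k-means on the embedding to call networks. A
network's per-sample activity is the mean z-scored expression of its member
genes.

k can be fixed (the typical use, reproducing a published clustering) or
scanned over a grid with :func:`choose_k` (silhouette argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .cohort_io import ExpressionMatrix
from .errors import (
    ConstantRowError,
    EmptyNetworkError,
    KExceedsPointsError,
    NoReferenceGenesError,
    PerplexityTooLargeError,
    TargetExceedsGenesError,
)


@dataclass
class GeneNetworkResult:
    """Output of a full network-calling run.

    ``labels`` maps each selected gene to a network id in 1..k; network 1 is
    the largest (canonical numbering by size, descending, ties broken by the
    lexicographically smallest member gene id). ``activity`` is the
    network × sample matrix of mean member-gene z-scores.
    """

    selected_genes: list[str]
    embedding: pd.DataFrame  # gene × (tsne1, tsne2)
    labels: pd.Series  # gene -> network id
    activity: pd.DataFrame  # network × sample
    k: int
    cv_threshold_used: float


def size_factor_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization of a raw count matrix.

    Each sample is divided by its size factor: the median, over the
    reference genes (those with a positive count in every sample, i.e. a
    positive geometric mean), of the ratio count / gene geometric mean.
    Genes containing zeros are excluded from the reference set but are
    still rescaled.

    Raises
    ------
    NoReferenceGenesError
        If no gene is positive in all samples.
    """
    x = counts.data.to_numpy(dtype=float)
    ref = (x > 0).all(axis=1)
    if not ref.any():
        raise NoReferenceGenesError("no gene has positive counts in every sample")
    log_geo = np.log(x[ref]).mean(axis=1)
    ratios = np.log(x[ref]) - log_geo[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    out = counts.data / size_factors
    return ExpressionMatrix(out, normalized=True)


def coefficient_of_variation(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene CV = sample sd (ddof=1) / mean; genes with mean 0 get CV 0."""
    mean = expr.data.mean(axis=1)
    sd = expr.data.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean == 0] = 0.0
    return cv


def select_variable_genes(
    expr: ExpressionMatrix, target_count: int, log1p: bool = False
) -> tuple[list[str], float]:
    """Pick the ``target_count`` genes with the highest coefficient of
    variation; returns (gene list, CV of the last included gene).

    Ties at the selection boundary are broken by lexicographic gene id, so
    the result is deterministic. With ``log1p=True`` the CV is computed on
    log1p-transformed values (an option for heavily skewed counts); the
    default is the linear normalized-count scale.

    Raises
    ------
    TargetExceedsGenesError
    """
    n_genes = expr.data.shape[0]
    if not (1 <= target_count <= n_genes):
        raise TargetExceedsGenesError(f"target_count {target_count} not in 1..{n_genes}")
    data = expr
    if log1p:
        data = ExpressionMatrix(np.log1p(expr.data), normalized=expr.normalized)
    cv = coefficient_of_variation(data)
    order = sorted(cv.index, key=lambda g: (-cv[g], g))
    selected = order[:target_count]
    return selected, float(cv[selected[-1]])


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene row to mean 0, sample sd 1 (ddof=1).

    Raises
    ------
    ConstantRowError
        If any row is constant (guaranteed absent after CV selection of
        varying genes).
    """
    mean = expr.data.mean(axis=1)
    sd = expr.data.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = expr.data.index[sd == 0].tolist()
        raise ConstantRowError(f"constant gene rows cannot be z-scored: {bad[:5]}")
    z = expr.data.sub(mean, axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, normalized=expr.normalized, zscored=True)


def embed_genes(
    z: ExpressionMatrix, perplexity: float = 30.0, seed: int = 0
) -> pd.DataFrame:
    """2-D t-SNE of the genes; samples are the feature dimensions.

    Deterministic given the seed (PCA initialisation, fixed random state).
    Requires n_genes > 3 * perplexity.

    Raises
    ------
    PerplexityTooLargeError
    """
    n = z.data.shape[0]
    if n <= 3 * perplexity:
        raise PerplexityTooLargeError(
            f"perplexity {perplexity} too large for {n} genes (need n > 3*perplexity)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=int(seed),
        method="barnes_hut",
    )
    coords = tsne.fit_transform(z.data.to_numpy())
    return pd.DataFrame(coords, index=z.data.index, columns=["tsne1", "tsne2"])


def _canonical_relabel(raw: np.ndarray, index: pd.Index) -> pd.Series:
    """Renumber clusters 1..k by size descending; ties by the
    lexicographically smallest member gene id."""
    ids = np.unique(raw)
    key = []
    for c in ids:
        members = index[raw == c]
        key.append((-len(members), min(members), c))
    mapping = {c: rank + 1 for rank, (_, _, c) in enumerate(sorted(key))}
    return pd.Series([mapping[c] for c in raw], index=index, name="network")


def cluster_genes(
    embedding: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 10
) -> pd.Series:
    """k-means on the 2-D embedding; best inertia over seeded restarts.

    Labels are canonical: network 1 is the largest, and so on.

    Raises
    ------
    KExceedsPointsError
    """
    n = embedding.shape[0]
    if not (1 <= k <= n):
        raise KExceedsPointsError(f"k={k} not in 1..{n} points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed))
    raw = km.fit_predict(embedding.to_numpy())
    return _canonical_relabel(raw, embedding.index)


def network_activity(z: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Network × sample activity: columnwise mean of member-gene rows.

    A single-gene network's activity equals that gene's row; the row for a
    merged pair of networks would be the size-weighted mean of their rows.

    Raises
    ------
    EmptyNetworkError
        If ``labels`` does not cover every gene of ``z`` or a declared
        network id has no members.
    """
    if not set(z.data.index) <= set(labels.index):
        missing = sorted(set(z.data.index) - set(labels.index))
        raise EmptyNetworkError(f"genes without a network label: {missing[:5]}")
    lab = labels.loc[z.data.index]
    present = set(lab)
    expected = set(range(1, max(present) + 1)) if present else set()
    if expected - present:
        raise EmptyNetworkError(f"empty networks: {sorted(expected - present)}")
    act = z.data.groupby(lab).mean()
    act.index.name = "network"
    return act.sort_index()


def choose_k(
    embedding: pd.DataFrame, k_grid: list[int], seed: int = 0, n_restarts: int = 10
) -> int:
    """Pick k from a grid by maximising the mean silhouette of the k-means
    partition on the embedding; ties go to the smaller k. A grid of one
    value returns that value without scoring."""
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    grid = sorted(set(int(k) for k in k_grid))
    if len(grid) == 1:
        return grid[0]
    best_k, best_score = None, -np.inf
    x = embedding.to_numpy()
    for k in grid:
        if k < 2 or k >= len(x):
            continue
        labels = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed)).fit_predict(x)
        score = silhouette_score(x, labels)
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise KExceedsPointsError("no k in the grid is feasible for this embedding")
    return best_k


def call_gene_networks(
    expr: ExpressionMatrix,
    target_count: int = 2000,
    k: int | None = None,
    k_grid: list[int] | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
    n_restarts: int = 10,
    log1p_cv: bool = False,
) -> GeneNetworkResult:
    """Run the full network-calling chain on a normalized expression matrix.

    Selection → z-scoring → embedding → clustering → activity. Exactly one
    of ``k`` (fixed) or ``k_grid`` (silhouette scan) must be given.
    """
    if (k is None) == (k_grid is None):
        raise ValueError("give exactly one of k or k_grid")
    selected, threshold = select_variable_genes(expr, target_count, log1p=log1p_cv)
    sub = ExpressionMatrix(expr.data.loc[selected], normalized=expr.normalized)
    z = zscore_genes(sub)
    emb = embed_genes(z, perplexity=perplexity, seed=seed)
    if k is None:
        k = choose_k(emb, k_grid, seed=seed, n_restarts=n_restarts)
    labels = cluster_genes(emb, k, seed=seed, n_restarts=n_restarts)
    activity = network_activity(z, labels)
    return GeneNetworkResult(
        selected_genes=selected,
        embedding=emb,
        labels=labels,
        activity=activity,
        k=int(k),
        cv_threshold_used=threshold,
    )
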