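"""Serum–allograft axis correlation and signature extraction.

Network activities are correlated against the serum protein panel with
Spearman's rank correlation; rows and columns of the resulting similarity
matrix are ordered by hierarchical clustering (distance 1 − Spearman rho
between profile vectors, complete linkage). Networks annotated as
metabolic (MB) or inflammatory (INF) are pooled into two axis activities,
and proteins passing an |rho| and p filter against an axis are ranked into
directional signatures:

* MB_up / MB_down, INF_up / INF_down — one axis, one direction;
* HEALTH = MB_up ∪ INF_down, INJURY = MB_down ∪ INF_up.

Axis membership (which networks are metabolic/inflammatory) is an input —
it comes from functional annotation of the networks, which is outside this
package's scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .cohort_io import ExpressionMatrix, ProteinPanel
from .errors import TooFewPairsError, UnknownNetworkIdError

logger = logging.getLogger(__name__)

SIGNATURE_CATEGORIES = ("MB_up", "MB_down", "INF_up", "INF_down", "HEALTH", "INJURY")


@dataclass
class AxisDefinition:
    """A named axis as a set of member networks (e.g. MB = networks
    related to metabolism). Member sets must be disjoint across axes."""

    axis_name: str
    member_networks: list[int]

    def __post_init__(self) -> None:
        if not self.member_networks:
            raise ValueError(f"axis {self.axis_name!r} has no member networks")


@dataclass
class AxisCorrelation:
    """Spearman rho/p/n matrices of (network or axis) × protein, plus the
    dendrogram leaf orders used to display them."""

    rho: pd.DataFrame
    pval: pd.DataFrame
    n_used: pd.DataFrame
    row_order: list
    col_order: list

    def ordered(self) -> pd.DataFrame:
        """The rho matrix reindexed to dendrogram order."""
        return self.rho.loc[self.row_order, self.col_order]


@dataclass
class Signature:
    """An ordered protein signature.

    ``proteins`` rows are sorted by the ranking statistic (max |rho| over
    the axis conditions the protein satisfies) descending, ties by protein
    id; at most ``k`` rows.
    """

    category: str
    proteins: pd.DataFrame  # index: protein; columns: rho_<axis>, p_<axis>, ..., stat, rank
    k: int

    @property
    def members(self) -> list[str]:
        return list(self.proteins.index)


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho and two-sided p (t approximation) with pairwise deletion.

    Ties receive average ranks. Returns (rho, p, n_used).

    Raises
    ------
    TooFewPairsError
        If fewer than 3 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise TooFewPairsError(f"only {n} complete pairs (need >= 3)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input yields rho = nan
        rho, p = spearmanr(x[mask], y[mask])
    return float(rho), float(p), n


def _profile_leaf_order(profiles: pd.DataFrame) -> list:
    """Dendrogram leaf order of the rows of ``profiles``: distance
    1 − Spearman rho between row profiles, complete linkage."""
    if profiles.shape[0] < 2:
        return list(profiles.index)
    if profiles.shape[0] == 2:
        return list(profiles.index)
    corr = profiles.T.corr(method="spearman")
    dist = (1.0 - corr).to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=1.0)  # uncorrelatable profiles: neutral distance
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="complete")
    return [profiles.index[i] for i in leaves_list(z)]


def correlate_activity_proteins(
    activity: pd.DataFrame, panel: ProteinPanel
) -> AxisCorrelation:
    """Full Spearman rho/p/n matrices of network activity × protein panel.

    Samples must match one-to-one (the time-matched cohort contract).
    Cells with too few complete pairs become NaN with a warning. Row and
    column orders come from complete-linkage clustering of the rho
    profiles (distance 1 − Spearman).
    """
    if list(activity.columns) != panel.sample_ids:
        raise ValueError("activity and panel must share an identical ordered sample set")
    nets = list(activity.index)
    prots = panel.protein_ids
    rho = pd.DataFrame(np.nan, index=nets, columns=prots)
    pval = pd.DataFrame(np.nan, index=nets, columns=prots)
    n_used = pd.DataFrame(0, index=nets, columns=prots, dtype=int)
    pdata = panel.data.to_numpy()
    adata = activity.to_numpy()
    for i, net in enumerate(nets):
        for j, prot in enumerate(prots):
            try:
                r, p, n = spearman(adata[i], pdata[j])
            except TooFewPairsError:
                logger.warning("too few pairs for network %s vs protein %s", net, prot)
                continue
            rho.loc[net, prot] = r
            pval.loc[net, prot] = p
            n_used.loc[net, prot] = n
    return AxisCorrelation(
        rho=rho,
        pval=pval,
        n_used=n_used,
        row_order=_profile_leaf_order(rho),
        col_order=_profile_leaf_order(rho.T),
    )


def axis_activity(
    z: ExpressionMatrix, labels: pd.Series, axes: Sequence[AxisDefinition]
) -> pd.DataFrame:
    """Axis × sample activity: mean z-scored expression over all genes of
    all member networks (gene-weighted — a 3-gene network contributes three
    times the weight of a single-gene network).

    Raises
    ------
    UnknownNetworkIdError
        If an axis references a network id absent from ``labels``.
    """
    seen: set[int] = set()
    for ax in axes:
        overlap = seen & set(ax.member_networks)
        if overlap:
            raise ValueError(f"networks {sorted(overlap)} appear in more than one axis")
        seen |= set(ax.member_networks)
    present = set(labels)
    rows = {}
    for ax in axes:
        unknown = set(ax.member_networks) - present
        if unknown:
            raise UnknownNetworkIdError(
                f"axis {ax.axis_name!r} references unknown networks {sorted(unknown)}"
            )
        genes = labels.index[labels.isin(ax.member_networks)]
        rows[ax.axis_name] = z.data.loc[genes].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "axis"
    return out


def axis_activity_from_networks(
    activity: pd.DataFrame,
    axes: Sequence[AxisDefinition],
    sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Axis activity from a network × sample activity matrix.

    With network sizes this reproduces the gene-weighted pooling of
    :func:`axis_activity`; without, member networks are weighted equally
    (logged, since it changes the semantics for unequal networks).
    """
    if sizes is None:
        logger.info("axis_activity_from_networks: no sizes given; weighting networks equally")
    rows = {}
    for ax in axes:
        unknown = set(ax.member_networks) - set(activity.index)
        if unknown:
            raise UnknownNetworkIdError(
                f"axis {ax.axis_name!r} references unknown networks {sorted(unknown)}"
            )
        sub = activity.loc[list(ax.member_networks)]
        if sizes is None:
            rows[ax.axis_name] = sub.mean(axis=0)
        else:
            w = sizes.loc[list(ax.member_networks)].to_numpy(dtype=float)
            rows[ax.axis_name] = pd.Series(
                (sub.to_numpy() * w[:, None]).sum(axis=0) / w.sum(), index=sub.columns
            )
    out = pd.DataFrame(rows).T
    out.index.name = "axis"
    return out


def protein_axis_table(axis_act: pd.DataFrame, panel: ProteinPanel) -> pd.DataFrame:
    """Per-protein Spearman rho/p/n against each axis activity row.

    Returns a DataFrame indexed by protein with columns
    ``rho_<axis>, p_<axis>, n_<axis>`` for every axis.
    """
    if list(axis_act.columns) != panel.sample_ids:
        raise ValueError("axis activity and panel must share an identical ordered sample set")
    cols: dict[str, list[float]] = {}
    for axis in axis_act.index:
        rhos, ps, ns = [], [], []
        for prot in panel.protein_ids:
            r, p, n = spearman(axis_act.loc[axis], panel.data.loc[prot])
            rhos.append(r)
            ps.append(p)
            ns.append(n)
        cols[f"rho_{axis}"] = rhos
        cols[f"p_{axis}"] = ps
        cols[f"n_{axis}"] = ns
    return pd.DataFrame(cols, index=pd.Index(panel.protein_ids, name="protein"))


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini–Hochberg adjusted p-values (for the optional FDR filter)."""
    p = p.copy()
    ok = p.notna()
    vals = p[ok].to_numpy()
    n = len(vals)
    order = np.argsort(vals)
    ranked = vals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty_like(ranked)
    adj[order] = np.clip(ranked, 0, 1)
    p.loc[ok] = adj
    return p


def extract_signature(
    table: pd.DataFrame,
    category: str,
    rho_min: float = 0.6,
    p_max: float = 0.05,
    k: int = 10,
    mb_axis: str = "MB",
    inf_axis: str = "INF",
    bh_correct: bool = False,
) -> Signature:
    """Filter and rank proteins into a directional signature.

    Per-axis conditions (on the columns of :func:`protein_axis_table`):
    ``up`` means rho > rho_min with p < p_max, ``down`` means
    rho <= −rho_min with p < p_max. HEALTH takes the union of MB_up and
    INF_down membership, INJURY the union of MB_down and INF_up — a protein
    qualifies on either axis alone or on both. The ranking statistic is the
    maximum |rho| over the qualifying axis conditions; the top ``k`` are
    returned (fewer if the filter yields fewer; an empty signature is not
    an error). ``bh_correct`` applies Benjamini–Hochberg across proteins
    per axis before filtering (off by default).
    """
    if category not in SIGNATURE_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if not (0.0 < rho_min <= 1.0) or not (0.0 < p_max < 1.0) or k < 1:
        raise ValueError("need rho_min in (0,1], p_max in (0,1), k >= 1")

    def cond(axis: str, direction: str) -> tuple[pd.Series, pd.Series]:
        rho = table[f"rho_{axis}"]
        p = table[f"p_{axis}"]
        if bh_correct:
            p = _bh_adjust(p)
        if direction == "up":
            passed = (rho > rho_min) & (p < p_max)
        else:
            passed = (rho <= -rho_min) & (p < p_max)
        return passed.fillna(False), rho.abs()

    parts = {
        "MB_up": [(mb_axis, "up")],
        "MB_down": [(mb_axis, "down")],
        "INF_up": [(inf_axis, "up")],
        "INF_down": [(inf_axis, "down")],
        "HEALTH": [(mb_axis, "up"), (inf_axis, "down")],
        "INJURY": [(mb_axis, "down"), (inf_axis, "up")],
    }[category]

    passed_any = pd.Series(False, index=table.index)
    stat = pd.Series(0.0, index=table.index)
    for axis, direction in parts:
        passed, absrho = cond(axis, direction)
        passed_any |= passed
        stat = stat.where(~passed, np.maximum(stat, absrho.fillna(0.0)))

    hits = table[passed_any].copy()
    hits["stat"] = stat[passed_any]
    hits = hits.sort_values(["stat"], ascending=False, kind="mergesort")
    # mergesort is stable; pre-sort by id for deterministic tie-breaks
    hits = hits.loc[sorted(hits.index)].sort_values("stat", ascending=False, kind="mergesort")
    hits = hits.head(k)
    hits["rank"] = np.arange(1, len(hits) + 1)
    return Signature(category=category, proteins=hits, k=int(k))
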