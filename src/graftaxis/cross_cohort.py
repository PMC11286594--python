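"""Cross-cohort reproducibility of gene networks.

Two cohorts are each clustered independently; reproducibility is measured
on the genes that survive variable-gene filtering in both. For every
network of cohort A the fraction of its common genes landing in each
network of cohort B is tabulated (a row-stochastic correspondence matrix),
and a network is flagged reproducible when at least a fraction θ of its
common genes map to one single B network (θ = 0.8 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UnlabeledCommonGeneError

logger = logging.getLogger(__name__)


@dataclass
class CorrespondenceTable:
    """Gene-overlap correspondence between two cohort clusterings.

    ``fraction`` is networksA × networksB; each row sums to 1 over the
    common genes of that A network (all-zero when the A network has no
    common genes). ``predominant`` flags A networks whose largest row entry
    reaches the threshold ``theta``.
    """

    common_genes: list[str]
    fraction: pd.DataFrame
    predominant: pd.Series
    theta: float


def common_variable_genes(genes_a: Sequence[str], genes_b: Sequence[str]) -> list[str]:
    """Sorted intersection of two variable-gene lists."""
    return sorted(set(genes_a) & set(genes_b))


def cluster_correspondence(
    labels_a: pd.Series,
    labels_b: pd.Series,
    common: Sequence[str],
    theta: float = 0.8,
) -> CorrespondenceTable:
    """Tabulate, per A network, where its common genes fall among B networks.

    fraction[i, j] = |genes of A-network i ∩ B-network j| / |A-network i ∩ common|.

    All A networks appear as rows, including those with no common genes
    (all-zero row, flag false, with a warning) so poorly covered clusters
    remain visible. The fractions are computed over common genes only.

    Raises
    ------
    UnlabeledCommonGeneError
        If a common gene lacks a label in either cohort.
    """
    if not (0.0 < theta <= 1.0):
        raise ValueError("theta must be in (0, 1]")
    common = list(common)
    for name, lab in (("A", labels_a), ("B", labels_b)):
        missing = sorted(set(common) - set(lab.index))
        if missing:
            raise UnlabeledCommonGeneError(
                f"common genes unlabeled in cohort {name}: {missing[:5]}"
            )
    nets_a = sorted(set(labels_a))
    nets_b = sorted(set(labels_b))
    la = labels_a.loc[common]
    lb = labels_b.loc[common]
    counts = pd.crosstab(la, lb).reindex(index=nets_a, columns=nets_b, fill_value=0)
    denom = counts.sum(axis=1)
    uncovered = denom.index[denom == 0].tolist()
    if uncovered:
        logger.warning(
            "cluster_correspondence: A networks with no common genes: %s", uncovered
        )
    frac = counts.div(denom.replace(0, np.nan), axis=0).fillna(0.0)
    frac.index.name, frac.columns.name = "network_a", "network_b"
    flags = (frac.max(axis=1) >= theta) & (denom > 0)
    flags.name = "predominant"
    return CorrespondenceTable(
        common_genes=common, fraction=frac, predominant=flags, theta=float(theta)
    )
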