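"""Signature validation: intrasignature correlation vs a random-set null,
and association of signature scores with clinical parameters.

A protein signature is considered validated when (1) its member proteins
correlate with each other across samples more strongly than random sets of
the same size drawn from the panel, and (2) its per-sample score (mean NPX
of member proteins) associates with allograft function. Ten random sets of
ten proteins are the default control, and "stronger than control" means
the signature's mean pairwise Spearman exceeds every null draw (a 95th
percentile rule is available as an alternative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .axes import spearman
from .cohort_io import ClinicalTable, ProteinPanel
from .errors import (
    InsufficientProteinsError,
    TooFewMembersError,
    TooFewPairsError,
    UnknownProteinError,
    UnknownVariableError,
)


@dataclass
class ClinicalAssociation:
    """Spearman association of a signature score with one clinical variable,
    plus the least-squares line for XY plotting. NaN fields mean the
    variable had too few complete pairs."""

    variable: str
    rho: float
    p: float
    n_used: int
    slope: float
    intercept: float


@dataclass
class ValidationConfig:
    n_sets: int = 10
    set_size: int = 10
    truncations: tuple[int, ...] = (3, 6, 10)
    null_rule: str = "max"  # or "percentile_95"
    exclude_members_from_null: bool = False
    clinical_variables: tuple[str, ...] = (
        "egfr",
        "creatinine",
        "proteinuria",
        "days_posttransplant",
    )
    seed: int = 0


@dataclass
class ValidationReport:
    """Validation outcome for one signature (or truncation of one)."""

    signature_id: str
    members: list[str]
    intra_rho: float
    null_rhos: list[float]
    null_mean: float
    null_sd: float
    null_rule: str
    exceeds_null: bool
    clinical_assocs: list[ClinicalAssociation] = field(default_factory=list)
    leave_one_out: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ValidationReport":
        with open(path) as fh:
            d = json.load(fh)
        d["clinical_assocs"] = [ClinicalAssociation(**a) for a in d["clinical_assocs"]]
        return cls(**d)


def _check_members(panel: ProteinPanel, members: Sequence[str]) -> list[str]:
    members = list(members)
    missing = sorted(set(members) - set(panel.protein_ids))
    if missing:
        raise UnknownProteinError(f"proteins absent from panel: {missing[:5]}")
    return members


def intrasignature_correlation(panel: ProteinPanel, members: Sequence[str]) -> float:
    """Mean Spearman rho over all unordered member pairs (the off-diagonal
    mean of the members' similarity matrix). Invariant to member order.

    Raises
    ------
    UnknownProteinError, TooFewMembersError
    """
    members = _check_members(panel, members)
    if len(members) < 2:
        raise TooFewMembersError("need at least 2 member proteins")
    sub = panel.data.loc[members]
    corr = sub.T.corr(method="spearman").to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(corr[iu].mean())


def random_set_null(
    panel: ProteinPanel,
    set_size: int = 10,
    n_sets: int = 10,
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> list[float]:
    """Intrasignature correlations of ``n_sets`` random protein sets.

    Each set is drawn without replacement from the panel minus ``exclude``
    (empty by default: random controls come from the full measured panel).
    Reproducible given the seed.

    Raises
    ------
    InsufficientProteinsError
    """
    pool = sorted(set(panel.protein_ids) - set(exclude))
    if set_size > len(pool):
        raise InsufficientProteinsError(
            f"cannot draw sets of {set_size} from {len(pool)} eligible proteins"
        )
    rng = np.random.default_rng(int(seed))
    out = []
    for _ in range(n_sets):
        draw = list(rng.choice(pool, size=set_size, replace=False))
        out.append(intrasignature_correlation(panel, draw))
    return out


def signature_score(panel: ProteinPanel, members: Sequence[str]) -> pd.Series:
    """Per-sample signature score: arithmetic mean of member NPX values."""
    members = _check_members(panel, members)
    if not members:
        raise TooFewMembersError("need at least 1 member protein")
    return panel.data.loc[members].mean(axis=0)


def clinical_association(
    score: pd.Series, clinical: ClinicalTable, variables: Sequence[str]
) -> list[ClinicalAssociation]:
    """Spearman of the score against each clinical variable, with pairwise
    deletion of missing clinical values; also returns the least-squares
    line (slope, intercept) through the complete pairs for XY plots.

    A variable with fewer than 3 complete pairs is reported with NaN
    statistics rather than raising.

    Raises
    ------
    UnknownVariableError
    """
    out = []
    for var in variables:
        if var not in clinical.data.columns:
            raise UnknownVariableError(f"clinical variable {var!r} not present")
        y = pd.to_numeric(clinical.data[var], errors="coerce").loc[score.index]
        try:
            rho, p, n = spearman(score.to_numpy(), y.to_numpy())
        except TooFewPairsError:
            out.append(ClinicalAssociation(var, float("nan"), float("nan"), 0,
                                           float("nan"), float("nan")))
            continue
        mask = score.notna() & y.notna()
        slope, intercept = np.polyfit(score[mask], y[mask], deg=1)
        out.append(ClinicalAssociation(var, rho, p, n, float(slope), float(intercept)))
    return out


def _exceeds(intra: float, null: Sequence[float], rule: str) -> bool:
    if rule == "max":
        return intra > max(null)
    if rule == "percentile_95":
        return intra > float(np.percentile(null, 95))
    raise ValueError(f"unknown null rule {rule!r}")


def validate_signature(
    panel: ProteinPanel,
    members: Sequence[str],
    clinical: ClinicalTable | None,
    config: ValidationConfig | None = None,
    signature_id: str = "signature",
    top_n: int | None = None,
    leave_one_out: bool = False,
) -> ValidationReport:
    """Assemble the full validation report for one signature.

    ``top_n`` truncates the (already ranked) member list before validation;
    ``leave_one_out`` additionally reports the intrasignature correlation
    with each member dropped in turn (reported alongside, never applied).
    """
    config = config or ValidationConfig()
    members = _check_members(panel, members)
    if top_n is not None:
        members = members[:top_n]
        signature_id = f"{signature_id}_top{top_n}"
    intra = intrasignature_correlation(panel, members)
    exclude = members if config.exclude_members_from_null else ()
    null = random_set_null(
        panel, set_size=config.set_size, n_sets=config.n_sets,
        seed=config.seed, exclude=exclude,
    )
    assocs = []
    if clinical is not None:
        score = signature_score(panel, members)
        assocs = clinical_association(score, clinical, config.clinical_variables)
    loo = {}
    if leave_one_out and len(members) > 2:
        for m in members:
            loo[m] = intrasignature_correlation(panel, [x for x in members if x != m])
    return ValidationReport(
        signature_id=signature_id,
        members=members,
        intra_rho=intra,
        null_rhos=[float(v) for v in null],
        null_mean=float(np.mean(null)),
        null_sd=float(np.std(null, ddof=1)) if len(null) > 1 else 0.0,
        null_rule=config.null_rule,
        exceeds_null=_exceeds(intra, null, config.null_rule),
        clinical_assocs=assocs,
        leave_one_out=loo,
    )


def validate_truncations(
    panel: ProteinPanel,
    members: Sequence[str],
    clinical: ClinicalTable | None,
    config: ValidationConfig | None = None,
    signature_id: str = "signature",
) -> dict[int, ValidationReport]:
    """Validate the top-n sub-signatures for every configured truncation
    (defaults: top 3, top 6, top 10, capped at the member count)."""
    config = config or ValidationConfig()
    out = {}
    for n in config.truncations:
        n_eff = min(int(n), len(list(members)))
        if n_eff < 2:
            continue
        out[n_eff] = validate_signature(
            panel, members, clinical, config, signature_id=signature_id, top_n=n_eff
        )
    return out
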