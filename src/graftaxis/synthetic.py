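"""Synthetic cohort generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: genes
organised in coregulated modules, each module driven by a latent per-sample
factor; modules grouped into two opposing axes (metabolism, MB, and
inflammation, INF) whose latent factors are anti-correlated; serum proteins
coupled to the axis factors at configurable Spearman strength; and clinical
kidney function (eGFR) coupled to the same factors.

Rank-correlation targets are hit exactly in expectation via a Gaussian
copula: a Spearman target rho_s translates to the Pearson parameter
``r_p = 2*sin(pi*rho_s/6)`` of a latent bivariate normal, and any strictly
monotone marginal transform (log-normal counts, the eGFR scale map) leaves
the rank correlation untouched.

All randomness flows from one integer seed through named sub-streams, so
e.g. changing the number of proteins cannot perturb the gene data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_io import ClinicalTable, CohortBundle, ExpressionMatrix, ProteinPanel
from .errors import InfeasibleCouplingError, InvalidConfigError

AXES = ("MB", "INF", "ECM", "none")

# Named sub-stream offsets: component i uses default_rng([_STREAMS[i], seed]).
_STREAMS = {"factors": 0, "genes": 1, "proteins": 2, "clinical": 3}


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: Pearson parameter hitting a Spearman target."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class ProteinCoupling:
    """One protein's rank-correlation target against one axis factor."""

    protein: int  # index into the panel, 0-based
    axis: str  # 'MB' or 'INF' (or 'ECM')
    rho: float  # target Spearman correlation in [-1, 1]


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults follow :func:`reference_scenario`.

    ``module_loading`` is the weight of the module factor in each member
    gene's latent value (gene = loading*factor + noise_sd*eps), so the
    gene–factor correlation is loading/sqrt(loading^2 + noise_sd^2).
    ``axis_coherence`` plays the same role one level up: module factors of
    an axis share that fraction of the axis factor. ``factor_correlation``
    is the (negative) latent Pearson correlation between the MB and INF
    axis factors — the two axes oppose each other across patients.
    """

    n_samples: int = 15
    n_modules: int = 15
    genes_per_module: int = 130
    n_background_genes: int = 650
    module_loading: float = 0.85
    axis_map: dict[int, str] = field(default_factory=dict)  # module id (1-based) -> axis
    n_proteins: int = 159
    protein_couplings: list[ProteinCoupling] = field(default_factory=list)
    clinical_couplings: tuple[float, float] = (0.6, -0.6)  # (egfr~MB, egfr~INF)
    factor_correlation: float = -0.7  # MB vs INF latent Pearson, in [-1, 0]
    axis_coherence: float = 0.7
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_modules < 1 or self.genes_per_module < 1:
            raise InvalidConfigError("n_samples>=2, n_modules>=1, genes_per_module>=1 required")
        if not (0.0 < self.module_loading <= 1.0):
            raise InvalidConfigError("module_loading must be in (0, 1]")
        if not (-1.0 <= self.factor_correlation <= 0.0):
            raise InvalidConfigError("factor_correlation must be in [-1, 0]")
        if not (0.0 <= self.axis_coherence <= 1.0):
            raise InvalidConfigError("axis_coherence must be in [0, 1]")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        for m, a in self.axis_map.items():
            if a not in AXES:
                raise InvalidConfigError(f"unknown axis {a!r} for module {m}")
            if not (1 <= m <= self.n_modules):
                raise InvalidConfigError(f"axis_map references module {m} outside 1..{self.n_modules}")
        for c in self.protein_couplings:
            if not (0 <= c.protein < self.n_proteins):
                raise InvalidConfigError(f"protein index {c.protein} out of range")
            if c.axis not in ("MB", "INF", "ECM"):
                raise InvalidConfigError(f"cannot couple to axis {c.axis!r}")
            if abs(c.rho) > 1:
                raise InvalidConfigError(f"|rho| must be <=1, got {c.rho}")
        for rho in self.clinical_couplings:
            if abs(rho) > 1:
                raise InvalidConfigError("clinical coupling |rho| must be <=1")

    # -- config round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protein_couplings"] = [[c.protein, c.axis, c.rho] for c in self.protein_couplings]
        d["clinical_couplings"] = list(self.clinical_couplings)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        d["protein_couplings"] = [
            ProteinCoupling(int(p), str(a), float(r)) for p, a, r in d.get("protein_couplings", [])
        ]
        d["clinical_couplings"] = tuple(d.get("clinical_couplings", (0.6, -0.6)))
        d["axis_map"] = {int(k): v for k, v in d.get("axis_map", {}).items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``gene_to_module`` maps each gene id to its module (0 = background),
    ``module_to_axis`` each module id to MB/INF/ECM/none, ``protein_axes``
    lists (protein id, axis, target Spearman rho) rows, and ``factors``
    holds the latent per-sample scores: rows ``MB``, ``INF``, ``ECM`` and
    ``M1..Mk`` (module factors).
    """

    gene_to_module: pd.Series
    module_to_axis: dict[int, str]
    protein_axes: pd.DataFrame  # columns: protein, axis, rho
    factors: pd.DataFrame  # factor × sample

    def module_members(self, module: int) -> list[str]:
        return self.gene_to_module.index[self.gene_to_module == module].tolist()

    def proteins_for_axis(self, axis: str, sign: int | None = None) -> list[str]:
        t = self.protein_axes[self.protein_axes["axis"] == axis]
        if sign is not None:
            t = t[np.sign(t["rho"]) == sign]
        return t["protein"].tolist()


def _rng(component: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[component], int(seed)])


def _axis_factors(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """MB/INF as an anti-correlated bivariate normal pair; ECM independent."""
    c = cfg.factor_correlation
    z = rng.standard_normal((2, cfg.n_samples))
    mb = z[0]
    inf = c * z[0] + math.sqrt(max(0.0, 1.0 - c * c)) * z[1]
    ecm = rng.standard_normal(cfg.n_samples)
    return pd.DataFrame([mb, inf, ecm], index=["MB", "INF", "ECM"])


def _joint_coupling_weights(
    targets: Mapping[str, float], factor_corr: Mapping[tuple[str, str], float]
) -> tuple[dict[str, float], float]:
    """Solve for weights a s.t. a latent ``sum_a a_i Z_i + resid*eps`` has the
    requested Pearson correlation with each axis factor; returns weights and
    the residual standard deviation.

    Raises InfeasibleCouplingError when the implied residual variance is
    negative (targets jointly unsatisfiable given the factor correlation).
    """
    axes = sorted(targets)
    r = np.array([targets[a] for a in axes])
    k = len(axes)
    sigma = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            c = factor_corr.get((axes[i], axes[j]), factor_corr.get((axes[j], axes[i]), 0.0))
            sigma[i, j] = sigma[j, i] = c
    a = np.linalg.solve(sigma, r)
    resid_var = 1.0 - float(r @ a)
    if resid_var < -1e-12:
        raise InfeasibleCouplingError(
            f"couplings {dict(targets)} jointly unsatisfiable (residual variance {resid_var:.3f})"
        )
    return dict(zip(axes, a)), math.sqrt(max(0.0, resid_var))


def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[CohortBundle, GroundTruth]:
    """Generate one cohort bundle plus its ground truth.

    Expression is log-normal: member-gene latent ``loading*M_j + noise_sd*eps``
    exponentiated around a per-gene baseline, so values live on a nonnegative
    normalized-count scale and the coefficient-of-variation filter behaves
    realistically (module members vary more than background). Proteins and
    eGFR are Gaussian-copula coupled to the axis factors; monotone marginal
    maps preserve the targeted Spearman correlations.

    Fully reproducible: same config and seed give bit-identical output.
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]

    # latent factors -----------------------------------------------------
    rng_f = _rng("factors", seed)
    axis_f = _axis_factors(config, rng_f)
    axis_f.columns = samples
    lam = config.axis_coherence
    module_rows = {}
    module_to_axis = {}
    for m in range(1, config.n_modules + 1):
        axis = config.axis_map.get(m, "none")
        module_to_axis[m] = axis
        u = rng_f.standard_normal(config.n_samples)
        if axis in ("MB", "INF", "ECM"):
            f = lam * axis_f.loc[axis].to_numpy() + math.sqrt(1 - lam * lam) * u
        else:
            f = u
        module_rows[f"M{m}"] = f
    factors = pd.concat([axis_f, pd.DataFrame(module_rows, index=samples).T])

    # genes --------------------------------------------------------------
    rng_g = _rng("genes", seed)
    n_member = config.n_modules * config.genes_per_module
    n_genes = n_member + config.n_background_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    assignment = np.concatenate(
        [
            np.repeat(np.arange(1, config.n_modules + 1), config.genes_per_module),
            np.zeros(config.n_background_genes, dtype=int),
        ]
    )
    base = rng_g.uniform(math.log(50.0), math.log(5000.0), size=n_genes)
    eps = rng_g.standard_normal((n_genes, config.n_samples))
    latent = config.noise_sd * eps
    for m in range(1, config.n_modules + 1):
        rows = assignment == m
        latent[rows] += config.module_loading * factors.loc[f"M{m}"].to_numpy()
    expr = np.exp(base[:, None] + latent)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=samples), normalized=True
    )
    gene_to_module = pd.Series(assignment, index=gene_ids, name="module")

    # proteins -----------------------------------------------------------
    rng_p = _rng("proteins", seed)
    protein_ids = [f"P{i + 1:03d}" for i in range(config.n_proteins)]
    targets_by_protein: dict[int, dict[str, float]] = {}
    for c in config.protein_couplings:
        targets_by_protein.setdefault(c.protein, {})[c.axis] = c.rho
    factor_corr = {("INF", "MB"): config.factor_correlation}
    npx = np.empty((config.n_proteins, config.n_samples))
    truth_rows = []
    for i in range(config.n_proteins):
        e = rng_p.standard_normal(config.n_samples)
        targets = targets_by_protein.get(i)
        if not targets:
            npx[i] = e
            continue
        pearson = {a: spearman_to_pearson(r) for a, r in targets.items()}
        weights, resid = _joint_coupling_weights(pearson, factor_corr)
        z = sum(w * axis_f.loc[a].to_numpy() for a, w in weights.items()) + resid * e
        npx[i] = z
        for a, r in targets.items():
            truth_rows.append({"protein": protein_ids[i], "axis": a, "rho": r})
    # NPX is a relative log2-like unit; shift to a plausible location.
    proteins = ProteinPanel(pd.DataFrame(3.0 + npx, index=protein_ids, columns=samples))
    protein_axes = pd.DataFrame(truth_rows, columns=["protein", "axis", "rho"])

    # clinical -----------------------------------------------------------
    rng_c = _rng("clinical", seed)
    rho_mb, rho_inf = config.clinical_couplings
    targets = {}
    if rho_mb:
        targets["MB"] = spearman_to_pearson(rho_mb)
    if rho_inf:
        targets["INF"] = spearman_to_pearson(rho_inf)
    e = rng_c.standard_normal(config.n_samples)
    if targets:
        weights, resid = _joint_coupling_weights(targets, factor_corr)
        egfr_z = sum(w * axis_f.loc[a].to_numpy() for a, w in weights.items()) + resid * e
    else:
        egfr_z = e
    from scipy.stats import norm

    egfr = 15.0 + 90.0 * norm.cdf(egfr_z)  # mL/min, monotone in the latent
    # creatinine tracks the inverse of function, plus measurement noise
    creat_z = -0.9 * egfr_z + math.sqrt(1 - 0.81) * rng_c.standard_normal(config.n_samples)
    creatinine = np.exp(0.3 + 0.5 * creat_z)
    baseline = np.exp(0.1 + 0.3 * rng_c.standard_normal(config.n_samples))
    days = np.exp(rng_c.uniform(math.log(30.0), math.log(3000.0), config.n_samples)).astype(int)
    proteinuria = np.exp(4.0 + 1.2 * rng_c.standard_normal(config.n_samples))
    p_rej = 1.0 / (1.0 + np.exp(-1.2 * axis_f.loc["INF"].to_numpy()))
    diagnosis = np.where(rng_c.uniform(size=config.n_samples) < p_rej, "rejection", "nonrejection")
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "days_posttransplant": days,
                "creatinine": creatinine,
                "creatinine_increase": creatinine - baseline,
                "egfr": egfr,
                "proteinuria": proteinuria,
                "diagnosis": diagnosis,
                "creatinine_pred_2mo": baseline
                + 0.05 * rng_c.standard_normal(config.n_samples),
                "creatinine_pred_12mo": baseline
                + 0.1 * rng_c.standard_normal(config.n_samples),
            },
            index=samples,
        )
    )

    bundle = CohortBundle(expression, proteins, clinical, provenance=f"synthetic(seed={seed})")
    truth = GroundTruth(gene_to_module, module_to_axis, protein_axes, factors)
    return bundle, truth


def generate_cohort_pair(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[CohortBundle, CohortBundle, GroundTruth, GroundTruth]:
    """Two cohorts sharing the same gene→module structure with independent
    factors and noise — the setting of a cross-cohort reproducibility check.

    Returns (bundle_a, bundle_b, truth_a, truth_b); the gene→module maps of
    the two truths are identical by construction.
    """
    seed = config.seed if seed is None else int(seed)
    a = generate_cohort(config, seed=seed)
    b = generate_cohort(config, seed=seed + 1_000_003)
    return a[0], b[0], a[1], b[1]


def reference_scenario() -> SyntheticConfig:
    """The named default scenario mirroring the study's dimensions.

    15 samples; 15 gene modules of 130 genes plus 650 background genes
    (~2,600 variable genes in total); modules 1, 3, 13, 14 form the MB axis
    and 4, 5, 6, 8, 9, 10, 11, 15 the INF axis (2 and 7 are ECM-like, 12
    unassigned); 159 serum proteins of which proteins 1–10 are planted
    INJURY-like (MB down / INF up) and 11–20 HEALTH-like (MB up / INF down)
    with rank-decreasing coupling strengths 0.9 → 0.7; eGFR is coupled +0.6
    to MB and −0.6 to INF.
    """
    axis_map = {m: "MB" for m in (1, 3, 13, 14)}
    axis_map.update({m: "INF" for m in (4, 5, 6, 8, 9, 10, 11, 15)})
    axis_map.update({2: "ECM", 7: "ECM", 12: "none"})
    couplings: list[ProteinCoupling] = []
    strengths = np.linspace(0.9, 0.7, 10)
    for j, r in enumerate(strengths):
        # INJURY-like: proteins 0..9 (P001..P010)
        couplings.append(ProteinCoupling(j, "MB", -float(r)))
        couplings.append(ProteinCoupling(j, "INF", float(r)))
        # HEALTH-like: proteins 10..19 (P011..P020)
        couplings.append(ProteinCoupling(10 + j, "MB", float(r)))
        couplings.append(ProteinCoupling(10 + j, "INF", -float(r)))
    return SyntheticConfig(
        n_samples=15,
        n_modules=15,
        genes_per_module=130,
        n_background_genes=650,
        module_loading=0.85,
        axis_map=axis_map,
        n_proteins=159,
        protein_couplings=couplings,
        clinical_couplings=(0.6, -0.6),
        factor_correlation=-0.7,
        axis_coherence=0.7,
        noise_sd=0.3,
        seed=0,
    )


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Write the ground truth as a TSV pair plus the factor matrix."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.gene_to_module.rename_axis("gene").to_frame().to_csv(
        out / "ground_truth_genes.tsv", sep="\t"
    )
    truth.protein_axes.to_csv(out / "ground_truth_proteins.tsv", sep="\t", index=False)
    truth.factors.rename_axis("factor").to_csv(out / "ground_truth_factors.tsv", sep="\t")
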