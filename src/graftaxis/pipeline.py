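"""End-to-end pipeline: cohort (files or synthetic) → gene networks →
optional cross-cohort comparison → serum axes → signatures → validation.

Every stage writes its artifacts as TSV/JSON under the output directory,
and a manifest records the full configuration, all seeds, input hashes and
the package version, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .axes import (
    AxisDefinition,
    axis_activity,
    correlate_activity_proteins,
    extract_signature,
    protein_axis_table,
)
from .cohort_io import (
    CohortBundle,
    align_samples,
    filter_low_variance_proteins,
    read_clinical,
    read_matrix,
    write_clinical,
    write_matrix,
)
from .cross_cohort import cluster_correspondence, common_variable_genes
from .errors import StageFailureError
from .networks import GeneNetworkResult, call_gene_networks, size_factor_normalize
from .synthetic import SyntheticConfig, generate_cohort, reference_scenario, write_ground_truth
from .validation import ValidationConfig, validate_truncations

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; round-trips through YAML."""

    # input: either synthetic mode or three file paths
    synthetic: bool = False
    synthetic_config: dict | None = None  # None in synthetic mode -> reference scenario
    expression_path: str | None = None
    proteins_path: str | None = None
    clinical_path: str | None = None
    raw_counts: bool = False
    min_protein_sd: float = 0.0
    # optional second cohort for the reproducibility stage
    expression_b_path: str | None = None
    theta: float = 0.8
    # gene networks
    target_count: int = 2000
    k: int | None = None
    k_grid: list[int] | None = None
    perplexity: float = 30.0
    n_restarts: int = 10
    log1p_cv: bool = False
    # axes: {"MB": [1, 3, ...], "INF": [...]}; empty in synthetic mode means
    # derive from the planted ground truth by majority vote per network
    axes_map: dict[str, list[int]] = field(default_factory=dict)
    rho_min: float = 0.6
    p_max: float = 0.05
    top_k: int = 10
    # validation
    n_sets: int = 10
    set_size: int = 10
    truncations: list[int] = field(default_factory=lambda: [3, 6, 10])
    null_rule: str = "max"
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


@dataclass
class RunReport:
    out_dir: str
    artifacts: dict[str, str]
    summary: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def derive_axes_from_truth(
    labels: pd.Series, gene_to_module: pd.Series, module_to_axis: Mapping[int, str]
) -> dict[str, list[int]]:
    """Map recovered networks to MB/INF by majority vote of the planted axis
    of their member genes (synthetic mode only; with real data the axis map
    comes from functional annotation and is user input)."""
    true_axis = gene_to_module.map(lambda m: module_to_axis.get(m, "none"))
    out: dict[str, list[int]] = {"MB": [], "INF": []}
    for net in sorted(set(labels)):
        members = labels.index[labels == net]
        votes = true_axis.loc[members].value_counts()
        if votes.empty:
            continue
        winner = votes.idxmax()
        if winner in out and votes.max() > len(members) / 2:
            out[winner].append(int(net))
    return {k: v for k, v in out.items() if v}


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageFailureError:
                raise
            except Exception as exc:  # noqa: BLE001 - boundary
                raise StageFailureError(name, exc) from exc
        return inner
    return wrap


@_stage("load")
def _load_cohort(cfg: RunConfig):
    truth = None
    if cfg.synthetic:
        scfg = (
            SyntheticConfig.from_dict(cfg.synthetic_config)
            if cfg.synthetic_config
            else reference_scenario()
        )
        bundle, truth = generate_cohort(scfg, seed=cfg.seed)
    else:
        if not (cfg.expression_path and cfg.proteins_path and cfg.clinical_path):
            raise FileNotFoundError(
                "non-synthetic mode needs expression_path, proteins_path, clinical_path"
            )
        expr = read_matrix(cfg.expression_path, kind="expression",
                           normalized=not cfg.raw_counts)
        panel = read_matrix(cfg.proteins_path, kind="protein")
        clinical = read_clinical(cfg.clinical_path)
        bundle = (expr, panel, clinical)
    return bundle, truth


@_stage("align_samples")
def _align(bundle_parts, provenance: str) -> CohortBundle:
    if isinstance(bundle_parts, CohortBundle):
        return bundle_parts
    expr, panel, clinical = bundle_parts
    return align_samples(expr, panel, clinical, provenance=provenance)


@_stage("networks")
def _networks(cfg: RunConfig, bundle: CohortBundle) -> GeneNetworkResult:
    expr = bundle.expression
    if cfg.raw_counts or not expr.normalized:
        expr = size_factor_normalize(expr)
    target = min(cfg.target_count, expr.data.shape[0])
    k, k_grid = cfg.k, cfg.k_grid
    if k is None and k_grid is None:
        k_grid = list(range(2, 21))
    return call_gene_networks(
        expr,
        target_count=target,
        k=k,
        k_grid=k_grid,
        perplexity=cfg.perplexity,
        seed=cfg.seed,
        n_restarts=cfg.n_restarts,
        log1p_cv=cfg.log1p_cv,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute the full analysis; returns a report with artifact paths and
    headline metrics. Raises StageFailureError naming the failing stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {}

    def save(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    parts, truth = _load_cohort(config)
    if config.synthetic:
        bundle = parts  # generate_cohort returns an aligned bundle
        write_matrix(bundle.expression, out / "expression.tsv")
        write_matrix(bundle.proteins, out / "proteins.tsv")
        write_clinical(bundle.clinical, out / "clinical.tsv")
        write_ground_truth(truth, out)
        for n in ("expression", "proteins", "clinical"):
            save(n, out / f"{n}.tsv")
    else:
        bundle = _align(parts, provenance="files")

    try:
        bundle = CohortBundle(
            bundle.expression,
            filter_low_variance_proteins(bundle.proteins, config.min_protein_sd),
            bundle.clinical,
            provenance=bundle.provenance,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageFailureError("protein_filter", exc) from exc

    result = _networks(config, bundle)
    pd.Series(result.selected_genes, name="gene").to_csv(
        out / "selected_genes.tsv", sep="\t", index=False
    )
    result.embedding.rename_axis("gene").to_csv(out / "embedding.tsv", sep="\t")
    result.labels.rename_axis("gene").to_frame().to_csv(out / "labels.tsv", sep="\t")
    result.activity.to_csv(out / "activity.tsv", sep="\t")
    for n in ("selected_genes", "embedding", "labels", "activity"):
        save(n, out / f"{n}.tsv")
    summary["k"] = result.k
    summary["n_selected_genes"] = len(result.selected_genes)
    summary["cv_threshold"] = result.cv_threshold_used

    if config.expression_b_path:
        # second cohort runs the network stage standalone, then correspondence
        try:
            expr_b = read_matrix(config.expression_b_path, kind="expression",
                                 normalized=not config.raw_counts)
            if config.raw_counts:
                expr_b = size_factor_normalize(expr_b)
            k_grid_b = config.k_grid
            if config.k is None and k_grid_b is None:
                k_grid_b = list(range(2, 21))
            res_b = call_gene_networks(
                expr_b,
                target_count=min(config.target_count, expr_b.data.shape[0]),
                k=config.k,
                k_grid=k_grid_b,
                perplexity=config.perplexity,
                seed=config.seed,
                n_restarts=config.n_restarts,
                log1p_cv=config.log1p_cv,
            )
            common = common_variable_genes(result.selected_genes, res_b.selected_genes)
            table = cluster_correspondence(result.labels, res_b.labels, common, config.theta)
            table.fraction.to_csv(out / "correspondence_fraction.tsv", sep="\t")
            table.predominant.rename_axis("network_a").to_frame().to_csv(
                out / "correspondence_flags.tsv", sep="\t"
            )
            save("correspondence_fraction", out / "correspondence_fraction.tsv")
            save("correspondence_flags", out / "correspondence_flags.tsv")
            summary["n_common_genes"] = len(common)
            summary["fraction_predominant"] = float(table.predominant.mean())
        except Exception as exc:  # noqa: BLE001
            raise StageFailureError("cross_cohort", exc) from exc

    # --- serum axes ----------------------------------------------------
    try:
        corr = correlate_activity_proteins(result.activity, bundle.proteins)
        corr.rho.rename_axis("network").to_csv(out / "network_protein_rho.tsv", sep="\t")
        corr.pval.rename_axis("network").to_csv(out / "network_protein_p.tsv", sep="\t")
        corr.ordered().rename_axis("network").to_csv(out / "network_protein_rho_ordered.tsv",
                                                     sep="\t")
        for n in ("network_protein_rho", "network_protein_p", "network_protein_rho_ordered"):
            save(n, out / f"{n}.tsv")

        axes_map = {k: list(v) for k, v in config.axes_map.items()}
        if not axes_map and config.synthetic:
            axes_map = derive_axes_from_truth(
                result.labels, truth.gene_to_module, truth.module_to_axis
            )
        if not axes_map:
            raise ValueError("axes_map is required (networks per axis, from annotation)")
        axes = [AxisDefinition(name, nets) for name, nets in sorted(axes_map.items())]
        z = _zscored_selected(bundle, result)
        axis_act = axis_activity(z, result.labels, axes)
        axis_act.to_csv(out / "axis_activity.tsv", sep="\t")
        save("axis_activity", out / "axis_activity.tsv")
        table = protein_axis_table(axis_act, bundle.proteins)
        table.to_csv(out / "protein_axis_table.tsv", sep="\t")
        save("protein_axis_table", out / "protein_axis_table.tsv")
        summary["axes_map"] = axes_map

        sigs = {}
        for cat in ("HEALTH", "INJURY", "MB_up", "MB_down", "INF_up", "INF_down"):
            sigs[cat] = extract_signature(
                table, cat, rho_min=config.rho_min, p_max=config.p_max, k=config.top_k
            )
        sig_rows = []
        for cat, sig in sigs.items():
            for prot, row in sig.proteins.iterrows():
                rec = {"category": cat, "protein": prot}
                rec.update({c: row[c] for c in sig.proteins.columns})
                sig_rows.append(rec)
        pd.DataFrame(sig_rows).to_csv(out / "signatures.tsv", sep="\t", index=False)
        save("signatures", out / "signatures.tsv")
        summary["signature_sizes"] = {c: len(s.members) for c, s in sigs.items()}
    except StageFailureError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailureError("serum_axes", exc) from exc

    # --- validation ----------------------------------------------------
    try:
        vcfg = ValidationConfig(
            n_sets=config.n_sets,
            set_size=config.set_size,
            truncations=tuple(config.truncations),
            null_rule=config.null_rule,
            seed=config.seed,
        )
        summary["validation"] = {}
        for cat in ("INJURY", "HEALTH"):
            members = sigs[cat].members
            if len(members) < 2:
                continue
            reports = validate_truncations(
                bundle.proteins, members, bundle.clinical, vcfg, signature_id=cat
            )
            for n, rep in reports.items():
                p = out / f"validation_{cat}_top{n}.json"
                rep.to_json(p)
                save(f"validation_{cat}_top{n}", p)
                summary["validation"][rep.signature_id] = {
                    "intra_rho": rep.intra_rho,
                    "exceeds_null": rep.exceeds_null,
                }
    except Exception as exc:  # noqa: BLE001
        raise StageFailureError("validation", exc) from exc

    manifest = {
        "package": "graftaxis",
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("expression", config.expression_path),
                ("proteins", config.proteins_path),
                ("clinical", config.clinical_path),
                ("expression_b", config.expression_b_path),
            )
            if p
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    save("manifest", out / "manifest.json")

    report = RunReport(out_dir=str(out), artifacts=artifacts, summary=summary)
    report.to_json(out / "run_report.json")
    return report


def _zscored_selected(bundle: CohortBundle, result: GeneNetworkResult):
    from .cohort_io import ExpressionMatrix
    from .networks import zscore_genes

    expr = bundle.expression
    sub = ExpressionMatrix(expr.data.loc[result.selected_genes], normalized=expr.normalized)
    return zscore_genes(sub)
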