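"""End-to-end analysis workflow behind a single run configuration.

For one tooth the pipeline: filters the analysis wear classes, superimposes
all modern specimens (GPA, optionally with bending-energy sliding), then per
wear class runs size tests, shape PCA, variance decomposition, CVA with
leave-one-out cross-validation, Mahalanobis distances with a neighbour-joining
tree, and the allometry test; archaeological specimens are projected into the
modern shape space and assigned by linear discriminant analysis, with
per-site summaries.  Every table is written as CSV next to a JSON sidecar
recording parameters, seed and software version, so reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bending import SlidingSpec
from .classification import (CVA, classify_unknowns, project_unknowns,
                             retain_components, summarize_assignments)
from .errors import ValidationError
from .io import (MorphometricDataset, assemble_dataset, default_role_layout,
                 filter_analysis_set, read_metadata, read_tps)
from .phenetics import neighbor_joining, write_newick
from .shape_stats import (allometry_regression, pca_shapes, size_tests,
                          variance_decomposition)
from .superimposition import gpa

logger = logging.getLogger("molargm")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    tps_path: str
    metadata_path: str
    output_dir: str
    tooth: str = "m1"
    grouping: str = "subspecies"       # subspecies | status | population | sex
    retention_threshold: float = 0.95
    n_perm: int = 999
    seed: int = 0
    slide: bool = True
    slide_iterations: int = 5
    n_fixed: int = 9
    n_semi: int = 66
    wear_classes: list[int] | None = None   # override of the default filter

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")


def _write_table(df: pd.DataFrame, path: Path, params: dict) -> None:
    df.to_csv(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(params, indent=2, default=str) + "\n", encoding="utf-8")


def load_dataset(config: RunConfig) -> MorphometricDataset:
    configs = read_tps(config.tps_path, apply_scale=True)
    roles, seg = default_role_layout(config.n_fixed, config.n_semi)
    k = config.n_fixed + config.n_semi
    configs = [
        c.with_roles(roles, seg) if c.k == k else c for c in configs
    ]
    metadata = read_metadata(config.metadata_path)
    return assemble_dataset(configs, metadata)


def run_pipeline(config: RunConfig, dataset: MorphometricDataset | None = None) -> dict:
    """Execute the full workflow and write all artifacts to the output dir.

    Returns a result bundle: a nested dict of in-memory tables keyed by
    stage and wear class.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = dict(seed=config.seed, version=__version__, tooth=config.tooth,
                 grouping=config.grouping,
                 retention_threshold=config.retention_threshold,
                 n_perm=config.n_perm, slide=config.slide)
    results: dict = {"config": stamp}
    log_lines: list[str] = []

    def _log(stage: str, **info) -> None:
        line = f"{stage}: " + ", ".join(f"{k}={v}" for k, v in info.items())
        logger.info(line)
        log_lines.append(line)

    stage = "load"
    try:
        if dataset is None:
            dataset = load_dataset(config)
        md = dataset.metadata
        modern_ids = md.index[md["provenance"] == "modern"].tolist()
        archaeo_ids = md.index[md["provenance"] == "archaeological"].tolist()
        _log("load", n=dataset.n, modern=len(modern_ids), archaeological=len(archaeo_ids))

        stage = "filter"
        modern = dataset.subset(modern_ids)
        filtered = filter_analysis_set(modern, config.tooth)
        if config.wear_classes is not None:
            keep = filtered.metadata.index[
                filtered.metadata["wear_class"].isin(config.wear_classes)
            ].tolist()
            filtered = filtered.subset(keep)
        _log("filter", tooth=config.tooth, kept=filtered.n,
             dropped=modern.n - filtered.n, seed=config.seed)

        stage = "gpa"
        sliding = SlidingSpec(max_outer_iterations=config.slide_iterations) \
            if config.slide else None
        aligned = gpa(filtered, sliding=sliding)
        _log("gpa", n=aligned.n, iterations=aligned.n_iterations,
             converged=aligned.converged, slid=aligned.slid)
        results["aligned"] = aligned

        stage = "wear_decomposition"
        wear_values = filtered.metadata["wear_class"]
        factors = pd.DataFrame({
            "wear_class": wear_values.astype(str),
            config.grouping: filtered.metadata[config.grouping].astype(str),
        })
        if wear_values.nunique() > 1:
            decomp = variance_decomposition(
                aligned, factors, n_perm=config.n_perm, seed=config.seed
            )
            _write_table(decomp.terms, out / f"{config.tooth}_variance_decomposition.csv",
                         stamp | {"factors": list(factors.columns)})
            results["variance_decomposition"] = decomp
            _log("variance_decomposition",
                 wear_pct=f"{decomp.terms.loc['wear_class', 'percent_variation']:.1f}")

        results["per_class"] = {}
        classes = sorted(wear_values.unique())
        seen_ids: set[str] = set()
        for wc in classes:
            tag = f"{config.tooth}_class{wc}"
            ids = filtered.metadata.index[wear_values == wc].tolist()
            assert not (set(ids) & seen_ids)
            seen_ids.update(ids)
            sub = filtered.subset(ids)
            groups = sub.metadata[config.grouping]
            if groups.nunique() < 2 or groups.value_counts().min() < 3:
                _log(f"{tag}", skipped="fewer than 2 usable groups")
                continue
            stage = f"{tag}:gpa"
            sub_aligned = gpa(sub, sliding=sliding)
            block: dict = {}

            stage = f"{tag}:size"
            report = size_tests(sub_aligned.centroid_sizes, groups)
            size_df = pd.DataFrame(
                dict(log_centroid_size=np.log(sub_aligned.centroid_sizes),
                     group=groups.to_numpy()),
                index=sub.metadata.index,
            )
            _write_table(size_df, out / f"{tag}_sizes.csv", stamp)
            _write_table(report.adjusted_p, out / f"{tag}_size_wilcoxon_bh.csv",
                         stamp | {"anova_F": report.anova_f, "anova_p": report.anova_p})
            block["size"] = report
            _log(f"{tag}:size", anova_p=f"{report.anova_p:.4g}")

            stage = f"{tag}:pca"
            space = pca_shapes(sub_aligned)
            pca_df = pd.DataFrame(dict(
                eigenvalue=space.eigenvalues,
                variance_proportion=space.variance_proportions,
            ))
            _write_table(pca_df, out / f"{tag}_pca.csv", stamp)
            block["pca"] = space
            _log(f"{tag}:pca", pc1=f"{space.variance_proportions[0]:.3f}",
                 pc2=f"{space.variance_proportions[1]:.3f}")

            stage = f"{tag}:cva"
            scores, n_keep = retain_components(space, config.retention_threshold)
            cva_res = CVA(scores, groups).fit()
            loo = cva_res.loo_classification()
            _write_table(loo.confusion, out / f"{tag}_cva_confusion.csv",
                         stamp | {"retained_components": n_keep,
                                  "overall_accuracy": loo.overall_accuracy})
            _write_table(cva_res.mahalanobis, out / f"{tag}_mahalanobis.csv", stamp)
            block["cva"] = cva_res
            block["loo"] = loo
            _log(f"{tag}:cva", retained=n_keep,
                 accuracy=f"{loo.overall_accuracy:.1f}%")

            stage = f"{tag}:tree"
            if len(cva_res.groups) >= 3:
                tree = neighbor_joining(cva_res.mahalanobis)
                write_newick(tree, out / f"{tag}_nj.nwk")
                block["tree"] = tree
                _log(f"{tag}:tree", leaves=len(tree.labels))

            stage = f"{tag}:allometry"
            allom = allometry_regression(sub_aligned, n_perm=config.n_perm,
                                         seed=config.seed)
            _write_table(
                pd.DataFrame([dict(r_squared=allom.r_squared, p=allom.p_value)]),
                out / f"{tag}_allometry.csv", stamp,
            )
            block["allometry"] = allom
            _log(f"{tag}:allometry", r2=f"{allom.r_squared:.3f}",
                 p=f"{allom.p_value:.4g}")

            stage = f"{tag}:unknowns"
            arch_ids = [
                i for i in archaeo_ids
                if md.loc[i, "tooth"] == config.tooth
                and (config.wear_classes is None
                     or md.loc[i, "wear_class"] in config.wear_classes)
                and md.loc[i, "wear_class"] == wc
            ]
            if arch_ids:
                unknown_cfgs = dataset.subset(arch_ids).configurations
                u_scores = project_unknowns(
                    sub_aligned, space, unknown_cfgs,
                    sliding=sliding,
                )[:, :n_keep]
                assignment = classify_unknowns(scores, groups, u_scores, ids=arch_ids)
                table = assignment.assignments.copy()
                table["site"] = md.loc[arch_ids, "population"].to_numpy()
                table["tooth"] = config.tooth
                table["wear_class"] = wc
                _write_table(table, out / f"{tag}_assignments.csv", stamp)
                block["assignments"] = table
                _log(f"{tag}:unknowns", n=len(arch_ids))
            results["per_class"][wc] = block

        stage = "assignment_summary"
        all_assign = [
            b["assignments"] for b in results["per_class"].values() if "assignments" in b
        ]
        if all_assign:
            pooled = pd.concat(all_assign)
            summary = summarize_assignments(pooled, by=["site"])
            overall = summarize_assignments(pooled)
            _write_table(summary, out / f"{config.tooth}_assignment_by_site.csv", stamp)
            _write_table(overall, out / f"{config.tooth}_assignment_overall.csv", stamp)
            results["assignment_summary"] = summary
            results["assignment_overall"] = overall
            _log("assignment_summary", n=len(pooled))
    except Exception as exc:
        raise ValidationError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _log("done", seconds=f"{time.time() - t_start:.1f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return results
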