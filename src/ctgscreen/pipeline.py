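"""End-to-end orchestration: cohort -> features -> selection -> evaluation.

``run_all`` executes the whole screening analysis with one configuration
object and writes every artifact (feature table, univariate report, RFE
path, grid surface, evaluation report, importance table, figures, log)
into a run directory with a provenance header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import svm
from .extract import extract_cohort
from .features import FeatureTable, build_table, preprocess
from .records import read_cohort_manifest, read_record, write_record
from .synthetic import CohortSpec, simulate_cohort
from .univariate import correlation_screen, univariate_table

log = logging.getLogger("ctgscreen")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    out_dir: str = "ctg_run"
    cohort_dir: str | None = None  # read this cohort instead of simulating
    seed: int = 0
    grid_exponents: list[int] = field(default_factory=lambda: svm.COARSE_EXPONENTS)
    cv_folds: int = svm.CV_FOLDS
    cv_repeats_search: int = 2
    cv_repeats_final: int = svm.CV_REPEATS_FINAL
    rfe_repeats: int = 1
    exclude_fetal_sex: bool = False
    ar_order: int = 12
    figures: bool = True
    n_healthy: int = 160
    n_iugr: int = 102

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_or_simulate(config: RunConfig) -> tuple[list, pd.DataFrame]:
    if config.cohort_dir:
        manifest = read_cohort_manifest(Path(config.cohort_dir) / "manifest.csv")
        records = [
            read_record(Path(config.cohort_dir) / row["path"])
            for _, row in manifest.iterrows()
        ]
        return records, manifest
    spec = CohortSpec(
        n_healthy=config.n_healthy, n_iugr=config.n_iugr, seed=config.seed
    )
    return simulate_cohort(spec)


def build_feature_table(config: RunConfig) -> FeatureTable:
    """Cohort in, preprocessed 32-feature table out."""
    records, _ = load_or_simulate(config)
    rows, labels, excluded = extract_cohort(records, ar_order=config.ar_order)
    if excluded:
        log.info("excluded %d subjects: %s", len(excluded), excluded)
    table = build_table(rows, labels)
    return preprocess(table)


def run_all(config: RunConfig) -> Path:
    """Run every stage and write all artifacts; returns the run directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    provenance = {"config": asdict(config), "config_hash": config.digest(),
                  "seed": config.seed}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))

    table = build_feature_table(config)
    if config.exclude_fetal_sex:
        table = svm.sex_excluded_variant(table)
    table.to_csv(out / "feature_table.csv")
    log.info("feature table: %d subjects x %d features", *table.X.shape)

    uni = univariate_table(table)
    uni.to_csv(out / "univariate_report.csv", index=False)
    corr, flagged = correlation_screen(table)
    corr.to_csv(out / "correlation_matrix.csv")

    rfe = svm.rfe_rank(table, folds=config.cv_folds,
                       repeats=config.rfe_repeats, seed=config.seed)
    (out / "rfe_path.json").write_text(json.dumps({
        "elimination_order": rfe.elimination_order,
        "path_j": {str(k): v for k, v in rfe.path_j.items()},
        "selected": rfe.selected,
    }, indent=1))
    selected = table.X.columns.intersection(rfe.selected)
    sel_table = FeatureTable(table.X[selected], table.y, table.provenance)

    train_ids, test_ids = svm.split_train_test(sel_table, seed=config.seed)
    train_table = FeatureTable(
        sel_table.X.loc[train_ids], sel_table.y.loc[train_ids], sel_table.provenance
    )
    grid = svm.grid_search(
        train_table, exponents=config.grid_exponents,
        folds=config.cv_folds, repeats=config.cv_repeats_search, seed=config.seed,
    )
    grid.grid.to_csv(out / "grid_surface.csv", index=False)
    log.info("grid optimum: C=2^%g gamma=2^%g J=%.3f",
             np.log2(grid.C_opt), np.log2(grid.gamma_opt), grid.J_opt)

    report = svm.evaluate(
        sel_table, train_ids, test_ids, grid.C_opt, grid.gamma_opt,
        folds=config.cv_folds, repeats=config.cv_repeats_final, seed=config.seed,
    )
    (out / "eval_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    imp = svm.feature_importance(
        sel_table, train_ids, grid.C_opt, grid.gamma_opt,
        folds=config.cv_folds, seed=config.seed,
    )
    imp.to_csv(out / "importance_report.csv", index=False)

    if config.figures:
        _plot_grid(grid.grid, out / "grid_surface.png")
        _plot_importance(imp, out / "importance.png")

    log.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out


def _plot_grid(grid: pd.DataFrame, path: Path) -> None:
    pivot = grid.pivot(index="log2_gamma", columns="log2_C", values="J")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.to_numpy(), shading="nearest")
    fig.colorbar(im, ax=ax, label="mean cross-validated J")
    ax.set_xlabel("log2 C")
    ax.set_ylabel("log2 gamma")
    ax.set_title("Youden J over the (C, gamma) grid")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_importance(imp: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 0.3 * len(imp) + 1.5))
    ax.barh(imp["feature"][::-1], imp["decrease_accuracy"][::-1])
    ax.set_xlabel("mean decrease in accuracy when removed")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Write a simulated cohort in the record CSV dialect with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, manifest = simulate_cohort(spec)
    for rec, (_, row) in zip(records, manifest.iterrows()):
        write_record(rec, out / row["path"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return out
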