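"""End-to-end pipeline configuration, dataset bundles and scoring.

``generate_dataset`` runs backbone -> GRN -> kinetics -> gold standard ->
stochastic simulation -> experiment emulation -> ground truths, and writes
a reproducible on-disk bundle: Matrix Market count matrices, TSV metadata,
ground truths and a JSON manifest. A single master seed deterministically
derives all stage seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .backbone import Backbone, predefined_backbone
from .experiment import (
    ExperimentDataset,
    LibrarySizeModel,
    generate_experiment,
    generate_paired_dataset,
)
from .grn import ReferenceNetwork, generate_grn
from .kinetics import KineticsConfig, sample_kinetics
from .metrics import (
    abwap,
    cellwise_auroc_aupr,
    dtw_align,
    velocity_correlation,
)
from .ssa import SSAConfig

__all__ = ["RunConfig", "generate_dataset", "write_bundle", "score"]


@dataclass
class RunConfig:
    """Configuration of one dataset-generation run."""

    backbone: str = "bifurcating"          # catalogue name or path to a JSON file
    num_tfs: int | None = None
    num_targets: int = 20
    num_hks: int = 10
    num_cells: int = 300
    mode: str = "snapshot"                 # or "time_series"
    total_time: float = 10.0
    burn_time: float = 2.0
    census_interval: float = 0.01
    num_simulations: int = 16
    library_size_median: float = 5000.0
    library_size_cv: float = 0.6
    reference_network: str | None = None   # optional edge-list TSV
    reference_counts: str | None = None    # optional Matrix Market matrix
    paired: bool = False                   # two kinetics draws, two trajectories
    seed: int = 1
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("num_targets", "num_hks", "num_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _resolve_backbone(spec: str) -> Backbone:
    p = Path(spec)
    if p.suffix == ".json" and p.exists():
        return Backbone.from_json(p)
    return predefined_backbone(spec)


def generate_dataset(cfg: RunConfig) -> ExperimentDataset:
    """Run the full pipeline for a configuration; write a bundle if
    ``cfg.out_dir`` is set. Idempotent per seed."""
    cfg.validate()
    backbone = _resolve_backbone(cfg.backbone)
    root = np.random.SeedSequence(cfg.seed)
    s_grn, s_kin, s_ssa, s_exp = [
        int(x) for x in root.generate_state(4) % (2 ** 31)
    ]
    ref = (
        ReferenceNetwork.from_tsv(cfg.reference_network)
        if cfg.reference_network
        else None
    )
    lib_model = (
        LibrarySizeModel.from_mtx(cfg.reference_counts)
        if cfg.reference_counts
        else LibrarySizeModel.parametric(cfg.library_size_median, cfg.library_size_cv)
    )
    ssa_cfg = SSAConfig(
        total_time=cfg.total_time,
        burn_time=cfg.burn_time,
        census_interval=cfg.census_interval,
        num_simulations=cfg.num_simulations,
        seed=s_ssa,
    )
    if cfg.paired:
        dataset = generate_paired_dataset(
            backbone,
            num_tfs=cfg.num_tfs,
            num_targets=cfg.num_targets,
            num_hks=cfg.num_hks,
            num_cells_per_trajectory=cfg.num_cells // 2,
            ssa_config=ssa_cfg,
            rng=s_exp,
        )
    else:
        grn = generate_grn(
            backbone, cfg.num_tfs, cfg.num_targets, cfg.num_hks, ref=ref, rng=s_grn
        )
        kinetics = sample_kinetics(grn, rng=s_kin)
        dataset = generate_experiment(
            grn,
            kinetics,
            num_cells=cfg.num_cells,
            mode=cfg.mode,
            ssa_config=ssa_cfg,
            lib_model=lib_model,
            rng=s_exp,
        )
    dataset.provenance["run_config"] = asdict(cfg)
    if cfg.out_dir:
        write_bundle(dataset, cfg.out_dir)
    return dataset


def _mmwrite(path: Path, matrix: np.ndarray) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(matrix))


def write_bundle(dataset: ExperimentDataset, out_dir: str | Path) -> Path:
    """Write a dataset bundle: counts_{unspliced,spliced,protein}{,_true}.mtx,
    cells.tsv, genes.tsv, velocity_gt.mtx, csni_gt.tsv, gold_standard/ and
    manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layers = {
        "counts_unspliced": dataset.counts_unspliced,
        "counts_spliced": dataset.counts_spliced,
        "counts_protein": dataset.counts_protein,
        "counts_unspliced_true": dataset.true_unspliced,
        "counts_spliced_true": dataset.true_spliced,
        "counts_protein_true": dataset.true_protein,
        "velocity_gt": dataset.velocity_gt,
    }
    for name, mat in layers.items():
        _mmwrite(out / f"{name}.mtx", mat)
    dataset.cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    dataset.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    dataset.csni_gt.to_csv(out / "csni_gt.tsv", sep="\t", index=False)
    if dataset.kinetics is not None:
        dataset.kinetics.gene_table().to_csv(out / "kinetics_genes.tsv", sep="\t", index=False)
        dataset.kinetics.interaction_table().to_csv(
            out / "kinetics_interactions.tsv", sep="\t", index=False
        )
    if dataset.gold_standard is not None:
        gdir = out / "gold_standard"
        gdir.mkdir(exist_ok=True)
        gs = dataset.gold_standard
        rows = []
        for i, e in enumerate(gs.edges):
            for p in gs.progressions[i]:
                rows.append({"edge": e.key, "percentage": p})
        pd.DataFrame(rows).to_csv(gdir / "progressions.tsv", sep="\t", index=False)
        _mmwrite(gdir / "expression.mtx", np.vstack(gs.matrices))
    manifest = {
        "num_cells": int(dataset.num_cells),
        "num_genes": int(dataset.num_genes),
        "files": sorted(f"{n}.mtx" for n in layers) + ["cells.tsv", "genes.tsv", "csni_gt.tsv"],
        "provenance": _jsonable(dataset.provenance),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def _read_bundle_cells(bundle: Path) -> pd.DataFrame:
    return pd.read_csv(bundle / "cells.tsv", sep="\t")


def score(
    bundle_path: str | Path,
    prediction_path: str | Path | None,
    metric: str,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Score a prediction against a bundle's ground truth.

    Metrics: ``abwap`` (paired-trajectory bundle; the prediction file is
    optional — by default the bundle's own expression series are aligned
    with DTW), ``velocity`` (prediction: velocity matrix .mtx, cells x
    genes), ``csni`` (prediction: TSV with cell, regulator, target, score).
    Writes and returns a per-unit scores table.
    """
    bundle = Path(bundle_path)
    cells = _read_bundle_cells(bundle)
    if metric == "velocity":
        gt = np.asarray(scipy.io.mmread(bundle / "velocity_gt.mtx").todense())
        pred = np.asarray(scipy.io.mmread(prediction_path).todense())
        rho = velocity_correlation(gt, pred)
        genes = pd.read_csv(bundle / "genes.tsv", sep="\t")["gene"]
        out = pd.DataFrame({"unit": genes, "metric": "velocity_correlation", "score": rho})
    elif metric == "csni":
        truth = pd.read_csv(bundle / "csni_gt.tsv", sep="\t")
        pred = pd.read_csv(prediction_path, sep="\t")
        auroc, aupr, per_cell = cellwise_auroc_aupr(truth, pred)
        out = pd.concat(
            [
                pd.DataFrame(
                    {"unit": per_cell.cell, "metric": "auroc", "score": per_cell.auroc}
                ),
                pd.DataFrame(
                    {"unit": per_cell.cell, "metric": "aupr", "score": per_cell.aupr}
                ),
                pd.DataFrame(
                    {
                        "unit": ["mean", "mean"],
                        "metric": ["auroc", "aupr"],
                        "score": [auroc, aupr],
                    }
                ),
            ],
            ignore_index=True,
        )
    elif metric == "abwap":
        if "trajectory" not in cells.columns:
            raise ValueError("abwap requires a paired-trajectory bundle")
        expr = np.asarray(scipy.io.mmread(bundle / "counts_spliced.mtx").todense())
        labels = cells["trajectory"].unique()
        if len(labels) != 2:
            raise ValueError("abwap requires exactly two trajectories")
        series, pts = [], []
        for lab in labels:
            idx = np.flatnonzero((cells["trajectory"] == lab).to_numpy())
            order = idx[np.argsort(cells["pseudotime"].to_numpy()[idx], kind="stable")]
            series.append(expr[order])
            pts.append(cells["pseudotime"].to_numpy()[order])
        path = dtw_align(series[0], series[1])
        out = pd.DataFrame(
            {"unit": ["alignment"], "metric": ["abwap"], "score": [abwap(path, *pts)]}
        )
    else:
        raise ValueError(f"unknown metric {metric!r}; choose abwap, velocity or csni")
    if out_path is not None:
        out.to_csv(out_path, sep="\t", index=False)
    return out
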