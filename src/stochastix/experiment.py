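"""Emulation of the single-cell profiling experiment.

Cells are sampled from the stochastic simulations, either as one
unsynchronised snapshot (allocation across state-network transitions
proportional to their lengths) or as a synchronised time series (equal
windows separated by gaps). Molecules are then sampled per cell: a library
size is drawn from a reference distribution of per-cell transcript totals
(empirical, or a log-normal stand-in), each molecule species receives a
capture rate drawn from N(1, 0.05), and the cell's observed counts are one
multinomial draw of exactly the library size with probabilities
proportional to capture rate times true abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .backbone import Backbone
from .grn import GeneRegulatoryNetwork, generate_grn
from .kinetics import Kinetics, KineticsConfig, ReactionSystem, build_reaction_system, sample_kinetics
from .ssa import SSAConfig, SimulationTrace, run_simulations
from .gold_standard import (
    GoldStandard,
    TrajectoryPosition,
    compute_pseudotime,
    map_cells_to_trajectory,
    simulate_gold_standard,
)
from .ground_truths import compute_cell_specific_grn, compute_velocity_ground_truth

__all__ = [
    "LibrarySizeModel",
    "SampledCells",
    "ExperimentDataset",
    "sample_cells_snapshot",
    "sample_cells_timeseries",
    "sample_molecules",
    "generate_experiment",
    "simulate_batches",
    "generate_paired_dataset",
]


class LibrarySizeModel:
    """Distribution of per-cell total transcript counts.

    Either empirical (totals of a reference count matrix) or a parametric
    log-normal stand-in; draws are positive integers.
    """

    def __init__(self, totals: np.ndarray | None = None,
                 median: float = 5000.0, cv: float = 0.6):
        self._totals = None if totals is None else np.asarray(totals, dtype=float)
        self._mu = np.log(median)
        self._sigma = float(np.sqrt(np.log(1.0 + cv ** 2)))

    @classmethod
    def parametric(cls, median: float = 5000.0, cv: float = 0.6) -> "LibrarySizeModel":
        return cls(None, median, cv)

    @classmethod
    def empirical(cls, totals: np.ndarray) -> "LibrarySizeModel":
        totals = np.asarray(totals, dtype=float)
        if (totals <= 0).any():
            totals = totals[totals > 0]
        if totals.size == 0:
            raise ValueError("no positive per-cell totals in reference")
        return cls(totals)

    @classmethod
    def from_mtx(cls, path, cells_axis: int = 1) -> "LibrarySizeModel":
        """Fit the empirical model to a Matrix Market count matrix
        (columns are cells by default)."""
        m = scipy.io.mmread(path)
        totals = np.asarray(m.sum(axis=0 if cells_axis == 1 else 1)).ravel()
        return cls.empirical(totals)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self._totals is not None:
            ls = self._totals[rng.integers(0, self._totals.size, size=n)]
        else:
            ls = np.exp(rng.normal(self._mu, self._sigma, size=n))
        return np.maximum(np.rint(ls).astype(np.int64), 1)


@dataclass
class SampledCells:
    """Cells drawn from simulation census rows."""

    sim_index: np.ndarray          # (n,)
    time: np.ndarray               # (n,) simulation time
    counts: np.ndarray             # (n, 3G) true molecule counts
    propensities: np.ndarray       # (n, 6G)
    positions: list[TrajectoryPosition]
    pseudotime: np.ndarray         # (n,)

    def __len__(self) -> int:
        return len(self.time)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing exactly to
    ``total`` (largest-remainder rounding, ties to the lowest index)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("allocation weights must have positive sum")
    quota = total * w / w.sum()
    alloc = np.floor(quota).astype(int)
    rem = quota - alloc
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-rem, kind="stable")
        alloc[order[:short]] += 1
    return alloc


def _pool_rows(traces: list[SimulationTrace]) -> tuple[np.ndarray, ...]:
    sim = np.concatenate(
        [np.full((t.main_rows).sum(), t.sim_index) for t in traces]
    )
    times = np.concatenate([t.times[t.main_rows] for t in traces])
    counts = np.vstack([t.counts[t.main_rows] for t in traces])
    props = np.vstack([t.propensities[t.main_rows] for t in traces])
    return sim, times, counts, props


def sample_cells_snapshot(
    traces: list[SimulationTrace],
    gs: GoldStandard,
    num_cells: int,
    rng: np.random.Generator | int | None = None,
) -> SampledCells:
    """Snapshot sampling: census rows (burn excluded) are mapped onto the
    trajectory; cells are allocated across state-network transitions
    proportionally to their lengths and drawn uniformly within each."""
    rng = np.random.default_rng(rng)
    sim, times, counts, props = _pool_rows(traces)
    positions = map_cells_to_trajectory(counts, gs)
    edge_of_row = np.array([p.edge_index for p in positions])
    L = gs.lengths
    alloc = _largest_remainder(L, num_cells)
    # transitions with no mapped rows give their quota to populated ones
    populated = np.array([np.any(edge_of_row == e) for e in range(len(L))])
    if not populated.any():
        raise ValueError("no simulation rows mapped to any transition")
    lost = int(alloc[~populated].sum())
    if lost:
        warnings.warn(
            f"{lost} cells reallocated away from transitions with no mapped states"
        )
        alloc[~populated] = 0
        extra = _largest_remainder(L * populated, lost)
        alloc = alloc + extra
    chosen: list[np.ndarray] = []
    for e in range(len(L)):
        if alloc[e] == 0:
            continue
        rows = np.flatnonzero(edge_of_row == e)
        replace = alloc[e] > rows.size
        chosen.append(rng.choice(rows, size=alloc[e], replace=bool(replace)))
    idx = np.concatenate(chosen)
    pos = [positions[i] for i in idx]
    return SampledCells(
        sim_index=sim[idx],
        time=times[idx],
        counts=counts[idx],
        propensities=props[idx],
        positions=pos,
        pseudotime=compute_pseudotime(pos, gs),
    )


def sample_cells_timeseries(
    traces: list[SimulationTrace],
    gs: GoldStandard,
    num_cells: int,
    total_time: float,
    k: int = 8,
    gap: float = 0.75,
    rng: np.random.Generator | int | None = None,
) -> SampledCells:
    """Time-series sampling: [0, T] is divided into ``k`` equal windows of
    width w = (T - (k-1) * gap) / k separated by gaps; num_cells/k cells are
    drawn uniformly from each window."""
    rng = np.random.default_rng(rng)
    w = (total_time - (k - 1) * gap) / k
    if w <= 0:
        raise ValueError(
            f"total_time={total_time} too small for k={k} windows with gap={gap}"
        )
    sim, times, counts, props = _pool_rows(traces)
    alloc = _largest_remainder(np.ones(k), num_cells)
    chosen = []
    for i in range(k):
        lo = i * (w + gap)
        hi = lo + w
        rows = np.flatnonzero((times >= lo) & (times <= hi))
        if rows.size == 0:
            warnings.warn(f"no census rows in sampling window [{lo:.3g}, {hi:.3g}]")
            continue
        replace = alloc[i] > rows.size
        chosen.append(rng.choice(rows, size=alloc[i], replace=bool(replace)))
    if not chosen:
        raise ValueError("no cells could be sampled from any time window")
    idx = np.concatenate(chosen)
    pos = map_cells_to_trajectory(counts[idx], gs)
    return SampledCells(
        sim_index=sim[idx],
        time=times[idx],
        counts=counts[idx],
        propensities=props[idx],
        positions=pos,
        pseudotime=compute_pseudotime(pos, gs),
    )


def sample_molecules(
    true_abundances: np.ndarray,
    lib_model: LibrarySizeModel | None = None,
    capture_rate_sd: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample observed counts: per cell one multinomial draw of its library
    size with probabilities proportional to capture rate x true abundance.

    Returns (observed counts, library sizes, capture rates). Capture rates
    are drawn once per molecule species from N(1, capture_rate_sd),
    truncated at 0. Cells with all-zero abundance get zero counts.
    """
    ab = np.atleast_2d(np.asarray(true_abundances, dtype=float))
    rng = np.random.default_rng(rng)
    lib_model = lib_model or LibrarySizeModel.parametric()
    n, S = ab.shape
    cr = np.maximum(rng.normal(1.0, capture_rate_sd, size=S), 0.0)
    ls = lib_model.draw(n, rng)
    obs = np.zeros((n, S), dtype=np.int64)
    weights = ab * cr
    zero_cells = 0
    for i in range(n):
        tot = weights[i].sum()
        if tot <= 0:
            zero_cells += 1
            ls[i] = 0
            continue
        obs[i] = rng.multinomial(ls[i], weights[i] / tot)
    if zero_cells:
        warnings.warn(f"{zero_cells} cells with zero total abundance got zero counts")
    return obs, ls, cr


# ----------------------------------------------------------------------
# dataset assembly
# ----------------------------------------------------------------------

@dataclass
class ExperimentDataset:
    """A sampled dataset with its ground truths.

    Count matrices are cells x genes; ``counts_unspliced``/``counts_spliced``
    /``counts_protein`` are the observed (sequenced) pre-mRNA, mature mRNA
    and protein layers, ``true_*`` the noise-free molecule counts.
    """

    counts_unspliced: np.ndarray
    counts_spliced: np.ndarray
    counts_protein: np.ndarray
    true_unspliced: np.ndarray
    true_spliced: np.ndarray
    true_protein: np.ndarray
    cells: pd.DataFrame
    genes: pd.DataFrame
    velocity_gt: np.ndarray
    csni_gt: pd.DataFrame
    gold_standard: GoldStandard | None = None
    kinetics: Kinetics | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def num_cells(self) -> int:
        return self.cells.shape[0]

    @property
    def num_genes(self) -> int:
        return self.genes.shape[0]


def generate_experiment(
    grn: GeneRegulatoryNetwork,
    kinetics: Kinetics,
    num_cells: int = 300,
    mode: str = "snapshot",
    ssa_config: SSAConfig | None = None,
    lib_model: LibrarySizeModel | None = None,
    capture_rate_sd: float = 0.05,
    timeseries_k: int = 8,
    timeseries_gap: float = 0.75,
    rng: np.random.Generator | int | None = None,
    label: str | None = None,
    sample_observed: bool = True,
) -> ExperimentDataset:
    """Run reactions -> gold standard -> SSA -> cell & molecule sampling ->
    ground truths for one (GRN, kinetics) model."""
    rng = np.random.default_rng(rng)
    cfg = ssa_config or SSAConfig()
    if cfg.seed is None:
        cfg.seed = int(rng.integers(0, 2 ** 31))
    system = build_reaction_system(grn, kinetics)
    gs = simulate_gold_standard(
        system, grn.backbone, total_time=cfg.total_time, burn_time=cfg.burn_time
    )
    traces = run_simulations(system, cfg)
    if mode == "snapshot":
        cells = sample_cells_snapshot(traces, gs, num_cells, rng)
    elif mode == "time_series":
        cells = sample_cells_timeseries(
            traces, gs, num_cells, cfg.total_time, timeseries_k, timeseries_gap, rng
        )
    else:
        raise ValueError("mode must be 'snapshot' or 'time_series'")

    G = system.num_genes
    true_x = cells.counts[:, :G]
    true_y = cells.counts[:, G:2 * G]
    true_z = cells.counts[:, 2 * G:]
    if sample_observed:
        obs, ls, cr = sample_molecules(cells.counts, lib_model, capture_rate_sd, rng)
    else:
        obs, ls, cr = cells.counts.copy(), cells.counts.sum(axis=1), np.ones(3 * G)
    velocity_gt = compute_velocity_ground_truth(cells.propensities, system)
    csni_gt = compute_cell_specific_grn(cells.counts.astype(float), system)
    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"cell{i + 1}" for i in range(len(cells))],
            "simulation": cells.sim_index,
            "sim_time": cells.time,
            "edge": [p.edge for p in cells.positions],
            "percentage": [p.percentage for p in cells.positions],
            "pseudotime": cells.pseudotime,
            "library_size": ls,
        }
    )
    if label is not None:
        cell_meta["trajectory"] = label
    return ExperimentDataset(
        counts_unspliced=obs[:, :G],
        counts_spliced=obs[:, G:2 * G],
        counts_protein=obs[:, 2 * G:],
        true_unspliced=true_x,
        true_spliced=true_y,
        true_protein=true_z,
        cells=cell_meta,
        genes=grn.gene_metadata(),
        velocity_gt=velocity_gt,
        csni_gt=csni_gt,
        gold_standard=gs,
        kinetics=kinetics,
        provenance={"ssa_seed": cfg.seed, "mode": mode, "capture_rates": cr},
    )


def _concat_datasets(parts: list[ExperimentDataset], key: str, labels: list[str]) -> ExperimentDataset:
    cells = []
    for ds, lab in zip(parts, labels):
        c = ds.cells.copy()
        c[key] = lab
        cells.append(c)
    first = parts[0]
    merged_cells = pd.concat(cells, ignore_index=True)
    merged_cells["cell_id"] = [f"cell{i + 1}" for i in range(len(merged_cells))]
    csni = []
    offset = 0
    for ds in parts:
        c = ds.csni_gt.copy()
        c["cell"] = c["cell"] + offset
        offset += ds.num_cells
        csni.append(c)
    return ExperimentDataset(
        counts_unspliced=np.vstack([d.counts_unspliced for d in parts]),
        counts_spliced=np.vstack([d.counts_spliced for d in parts]),
        counts_protein=np.vstack([d.counts_protein for d in parts]),
        true_unspliced=np.vstack([d.true_unspliced for d in parts]),
        true_spliced=np.vstack([d.true_spliced for d in parts]),
        true_protein=np.vstack([d.true_protein for d in parts]),
        cells=merged_cells,
        genes=first.genes,
        velocity_gt=np.vstack([d.velocity_gt for d in parts]),
        csni_gt=pd.concat(csni, ignore_index=True),
        gold_standard=first.gold_standard,
        kinetics=first.kinetics,
        provenance={
            key: labels,
            "parts": [d.provenance for d in parts],
            "kinetics_k": [
                None if d.kinetics is None
                else d.kinetics.interaction_table()["k"].tolist()
                for d in parts
            ],
        },
    )


def simulate_batches(
    backbone: Backbone,
    num_batches: int,
    num_tfs: int | None = None,
    num_targets: int = 20,
    num_hks: int = 10,
    num_cells_per_batch: int = 150,
    ssa_config: SSAConfig | None = None,
    kinetics_config: KineticsConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ExperimentDataset:
    """Batch effects: one module network and GRN, but independently drawn
    kinetics per batch, each followed by the full downstream pipeline."""
    rng = np.random.default_rng(rng)
    grn = generate_grn(backbone, num_tfs, num_targets, num_hks, rng=rng)
    parts = []
    for b in range(num_batches):
        kin = sample_kinetics(grn, rng=rng, config=kinetics_config)
        cfg = SSAConfig(**{**vars(ssa_config or SSAConfig())})
        cfg.seed = int(rng.integers(0, 2 ** 31))
        parts.append(
            generate_experiment(
                grn, kin, num_cells_per_batch, "snapshot", cfg, rng=rng
            )
        )
    return _concat_datasets(parts, "batch", [f"batch{b + 1}" for b in range(num_batches)])


def generate_paired_dataset(
    backbone: Backbone,
    num_tfs: int | None = None,
    num_targets: int = 20,
    num_hks: int = 10,
    num_cells_per_trajectory: int = 150,
    ssa_config: SSAConfig | None = None,
    kinetics_config: KineticsConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ExperimentDataset:
    """Trajectory-alignment dataset: one GRN, two independent kinetics draws,
    two gold standards; the combined cells carry a trajectory label and
    per-trajectory pseudotimes rescaled to [0, 1]."""
    rng = np.random.default_rng(rng)
    grn = generate_grn(backbone, num_tfs, num_targets, num_hks, rng=rng)
    parts = []
    for t in range(2):
        kin = sample_kinetics(grn, rng=rng, config=kinetics_config)
        cfg = SSAConfig(**{**vars(ssa_config or SSAConfig())})
        cfg.seed = int(rng.integers(0, 2 ** 31))
        parts.append(
            generate_experiment(
                grn, kin, num_cells_per_trajectory, "snapshot", cfg, rng=rng
            )
        )
    return _concat_datasets(parts, "trajectory", ["traj1", "traj2"])
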