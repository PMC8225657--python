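"""Noise-free ground-truth trajectory and cell-to-trajectory mapping.

For every edge of the backbone's state network a reference ("gold
standard") expression branch is produced by deterministic mean-field
integration of the same propensity functions used by the stochastic
engine, with each branch starting from the end state of its upstream
branch and only the modules flagged on that edge allowed to change.
Simulated cells are then mapped onto the branch position whose TF mRNA
profile correlates best with theirs, which yields each cell's geodesic
pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import rankdata

from .backbone import Backbone, StateEdge
from .kinetics import ReactionSystem

__all__ = [
    "GoldStandard",
    "TrajectoryPosition",
    "simulate_gold_standard",
    "map_cells_to_trajectory",
    "compute_pseudotime",
]


@dataclass(frozen=True)
class TrajectoryPosition:
    """A position on the ground-truth trajectory."""

    edge: str               # state-edge key "from->to"
    edge_index: int
    percentage: float       # progression along the edge, in [0, 1]
    pseudotime: float       # geodesic distance from the start, rescaled to [0, 1]


@dataclass
class GoldStandard:
    backbone: Backbone
    edges: list[StateEdge]
    matrices: list[np.ndarray]          # per edge: (points, 3G) expression
    progressions: list[np.ndarray]      # per edge: progression in [0, 1]
    start_dist: np.ndarray              # geodesic distance from start to edge source
    total_length: float
    feature_idx: np.ndarray             # columns used for correlation mapping
    state_expression: dict[str, np.ndarray]
    masks: list[np.ndarray] = field(default_factory=list)  # per-edge transcription masks

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e.length for e in self.edges])

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All branch rows stacked: (matrix, edge index per row, pct per row)."""
        mat = np.vstack(self.matrices)
        edge_idx = np.concatenate(
            [np.full(len(p), i) for i, p in enumerate(self.progressions)]
        )
        pct = np.concatenate(self.progressions)
        return mat, edge_idx, pct

    def row_pseudotime(self) -> np.ndarray:
        """Unit pseudotime of every stacked gold-standard row."""
        _, edge_idx, pct = self.stacked()
        L = self.lengths
        return (self.start_dist[edge_idx] + pct * L[edge_idx]) / self.total_length


def _edge_order_and_distances(backbone: Backbone) -> tuple[list[StateEdge], np.ndarray]:
    """Breadth-first edge order from the start state with geodesic distances
    (distance from start to each edge's source along first-discovery paths)."""
    dist: dict[str, float] = {backbone.start_state: 0.0}
    order: list[StateEdge] = []
    start_dist: list[float] = []
    frontier = [backbone.start_state]
    remaining = list(backbone.state_network)
    while frontier:
        s = frontier.pop(0)
        for e in [e for e in remaining if e.from_state == s]:
            remaining.remove(e)
            order.append(e)
            start_dist.append(dist[s])
            if e.to_state not in dist:
                dist[e.to_state] = dist[s] + e.length
                frontier.append(e.to_state)
    if remaining:
        keys = ", ".join(e.key for e in remaining)
        raise ValueError(f"state edges unreachable from start_state: {keys}")
    return order, np.asarray(start_dist)


def simulate_gold_standard(
    system: ReactionSystem,
    backbone: Backbone,
    total_time: float = 10.0,
    burn_time: float = 2.0,
    census_interval: float = 0.05,
) -> GoldStandard:
    """Integrate the mean-field dynamics branch by branch.

    Branch durations are proportional to the state-edge lengths, scaled so
    the longest root-to-tip geodesic spans ``total_time`` (the span of the
    stochastic simulations). The start state's expression is the mean-field
    burn-phase end state.
    """
    order, start_dist = _edge_order_and_distances(backbone)
    L = np.array([e.length for e in order])
    total_length = float((start_dist + L).max())
    time_unit = total_time / total_length

    G = system.num_genes
    genes = system.grn.genes
    module_of = {g.name: g.module for g in genes}
    active_sets = backbone.state_module_sets()

    def mask_for(active: set[str]) -> np.ndarray:
        m = np.ones(G)
        for i, g in enumerate(genes):
            if g.kind == "tf" and g.module not in active:
                m[i] = 0.0
        return m

    def integrate(s0: np.ndarray, mask: np.ndarray, duration: float, n_pts: int):
        sol = solve_ivp(
            lambda t, s: system.mean_field_rhs(np.clip(s, 0.0, None), mask),
            (0.0, duration),
            s0,
            t_eval=np.linspace(0.0, duration, n_pts),
            method="LSODA",
            rtol=1e-6,
            atol=1e-8,
        )
        return np.clip(sol.y.T, 0.0, None)

    # burn: only burn-flagged genes transcribe, from the zero state
    burn_mask = system.burn_genes.astype(float)
    if burn_time > 0:
        burn = integrate(np.zeros(3 * G), burn_mask, burn_time, 20)
        root_expr = burn[-1]
    else:
        root_expr = np.zeros(3 * G)

    state_expr: dict[str, np.ndarray] = {backbone.start_state: root_expr}
    matrices, progressions, masks = [], [], []
    for e in order:
        duration = e.length * time_unit
        n_pts = max(8, int(np.ceil(duration / census_interval)) + 1)
        mask = mask_for(active_sets[e.to_state])
        branch = integrate(state_expr[e.from_state].copy(), mask, duration, n_pts)
        matrices.append(branch)
        progressions.append(np.linspace(0.0, 1.0, n_pts))
        masks.append(mask)
        state_expr.setdefault(e.to_state, branch[-1])

    tf_idx = np.array([i for i, g in enumerate(genes) if g.kind == "tf"], dtype=np.int64)
    # mapping features: mature mRNA and protein of the TFs (TFs drive the
    # backbone; the protein layer adds a smoother, higher-count signal)
    feature_idx = np.concatenate([G + tf_idx, 2 * G + tf_idx])
    return GoldStandard(
        backbone=backbone,
        edges=order,
        matrices=matrices,
        progressions=progressions,
        start_dist=start_dist,
        total_length=total_length,
        feature_idx=feature_idx,
        state_expression=state_expr,
        masks=masks,
    )


def map_cells_to_trajectory(
    cells: np.ndarray, gs: GoldStandard
) -> list[TrajectoryPosition]:
    """Assign each cell the gold-standard position of highest Spearman
    correlation over TF mRNA features (ties resolved to the earliest
    pseudotime; zero-variance cells map to the trajectory start)."""
    cells = np.atleast_2d(np.asarray(cells, dtype=float))
    mat, edge_idx, pct = gs.stacked()
    F = gs.feature_idx
    if cells.shape[1] == mat.shape[1]:
        cf = cells[:, F]
    elif cells.shape[1] == len(F):
        cf = cells
    else:
        raise ValueError(
            f"cells have {cells.shape[1]} features; expected {mat.shape[1]} "
            f"species or {len(F)} TF mRNA features"
        )
    gf = mat[:, F]
    row_pt = gs.row_pseudotime()

    # Spearman correlation = Pearson correlation of ranks
    cr = rankdata(cf, axis=1).astype(float)
    gr = rankdata(gf, axis=1).astype(float)
    cr -= cr.mean(axis=1, keepdims=True)
    gr -= gr.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(cr, axis=1)
    gn = np.linalg.norm(gr, axis=1)
    zero_var_cells = cn == 0
    zero_var_rows = gn == 0
    cn[zero_var_cells] = 1.0
    gn[zero_var_rows] = 1.0
    corr = (cr / cn[:, None]) @ (gr / gn[:, None]).T
    corr[:, zero_var_rows] = -np.inf
    if zero_var_cells.any():
        warnings.warn(
            f"{int(zero_var_cells.sum())} zero-variance cells mapped to the trajectory start"
        )

    L = gs.lengths
    positions = []
    start_pos = TrajectoryPosition(gs.edges[0].key, 0, 0.0, 0.0)
    for i in range(cells.shape[0]):
        if zero_var_cells[i]:
            positions.append(start_pos)
            continue
        best = corr[i].max()
        cand = np.flatnonzero(corr[i] >= best - 1e-12)
        j = cand[np.argmin(row_pt[cand])]
        e = int(edge_idx[j])
        positions.append(
            TrajectoryPosition(gs.edges[e].key, e, float(pct[j]), float(row_pt[j]))
        )
    return positions


def compute_pseudotime(
    positions: list[TrajectoryPosition], gs: GoldStandard
) -> np.ndarray:
    """Unit pseudotime: (upstream geodesic length + percentage * edge length)
    divided by the total root-to-tip path length."""
    L = gs.lengths
    return np.array(
        [
            (gs.start_dist[p.edge_index] + p.percentage * L[p.edge_index])
            / gs.total_length
            for p in positions
        ]
    )
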