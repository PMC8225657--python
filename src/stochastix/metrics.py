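"""Evaluation metrics for trajectory alignment, RNA velocity and
cell-specific network inference.

* Trajectory alignment is scored with ABWAP (Area Between Worst Alignment
  and Prediction): given an alignment path over two unit-pseudotime series,
  1 minus the area under the curve (pt1 + pt2, |pt1 - pt2|). A perfect
  alignment of matching pseudotimes scores 1; the worst possible monotone
  path (one series fully consumed before the other starts) scores 0.
* RNA velocity is scored per gene by Spearman correlation with the
  ground-truth velocity, and per trajectory waypoint by the cosine between
  the locally averaged embedded velocity and the local trajectory direction.
* Cell-specific GRNs are scored per cell by AUROC / AUPR after keeping each
  cell's top-scoring interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "AlignmentPath",
    "dtw_align",
    "abwap",
    "velocity_correlation",
    "velocity_arrow_cosine",
    "cellwise_auroc_aupr",
    "pca_embedding",
]


@dataclass
class AlignmentPath:
    """A monotone warping path: index pairs from (0, 0) to (n-1, m-1)."""

    pairs: list[tuple[int, int]]
    cost: float = float("nan")

    def validate(self, n: int, m: int) -> list[str]:
        v = []
        if not self.pairs:
            return ["empty path"]
        if self.pairs[0] != (0, 0):
            v.append("path must start at (0, 0)")
        if self.pairs[-1] != (n - 1, m - 1):
            v.append("path must end at the last indices of both series")
        for (i0, j0), (i1, j1) in zip(self.pairs[:-1], self.pairs[1:]):
            if i1 < i0 or j1 < j0:
                v.append("path indices must be non-decreasing")
                break
            if i1 == i0 and j1 == j0:
                v.append("consecutive path steps must advance at least one index")
                break
        return v

    @property
    def i(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs])

    @property
    def j(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])


def dtw_align(
    series_a: np.ndarray, series_b: np.ndarray, distance: str = "euclidean"
) -> AlignmentPath:
    """Classical dynamic-time-warping alignment of two series.

    Series are (time, features) matrices (1-D input is treated as a single
    feature). Returns the optimal monotone path under the chosen pointwise
    distance, with steps (i+1, j), (i, j+1) or (i+1, j+1).
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.shape[0] == 1 and np.ndim(series_a) == 1:
        a = a.T
    if b.shape[0] == 1 and np.ndim(series_b) == 1:
        b = b.T
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    d = cdist(a, b, metric=distance)
    n, m = d.shape
    D = np.full((n, m), np.inf)
    D[0, 0] = d[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, D[i - 1, j])
            if j > 0:
                best = min(best, D[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1])
            D[i, j] = d[i, j] + best
    # backtrack, preferring the diagonal
    pairs = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        options = []
        if i > 0 and j > 0:
            options.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            options.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            options.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(options, key=lambda o: o[0])
        pairs.append((i, j))
    pairs.reverse()
    return AlignmentPath(pairs, cost=float(D[n - 1, m - 1]))


def abwap(path: AlignmentPath, pt1: np.ndarray, pt2: np.ndarray) -> float:
    """ABWAP score of an alignment path over two unit-pseudotime vectors.

    1 - trapezoidal area under (x, y) = (pt1[i] + pt2[j], |pt1[i] - pt2[j]|)
    along the path; lies in [0, 1] and equals 1 iff the aligned pseudotimes
    agree everywhere along the path.
    """
    pt1 = np.asarray(pt1, dtype=float)
    pt2 = np.asarray(pt2, dtype=float)
    i, j = path.i, path.j
    x = pt1[i] + pt2[j]
    y = np.abs(pt1[i] - pt2[j])
    return float(1.0 - np.trapezoid(y, x))


def velocity_correlation(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Per-gene Spearman correlation between ground-truth and predicted
    velocity (across cells); NaN for zero-variance genes."""
    gt = np.asarray(gt, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    rg = rankdata(gt, axis=0).astype(float)
    rp = rankdata(pred, axis=0).astype(float)
    rg -= rg.mean(axis=0)
    rp -= rp.mean(axis=0)
    ng = np.linalg.norm(rg, axis=0)
    npred = np.linalg.norm(rp, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rg * rp).sum(axis=0) / (ng * npred)
    rho[(ng == 0) | (npred == 0)] = np.nan
    return rho


def pca_embedding(X: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Deterministic PCA-style 2-D projection (SVD with a fixed sign
    convention), the bundled default embedding for the arrow-cosine metric."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude loading of each component positive
    for c in range(Vt.shape[0]):
        k = np.argmax(np.abs(Vt[c]))
        if Vt[c, k] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    return U[:, :n_components] * s[:n_components]


def velocity_arrow_cosine(
    embedding: np.ndarray,
    geodesic: np.ndarray,
    velocity_embedded: np.ndarray,
    num_waypoints: int = 100,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Per-waypoint cosine between the kernel-averaged embedded velocity and
    the local trajectory direction.

    Waypoints are spread uniformly over the geodesic coordinate; each cell
    is weighted by a Gaussian kernel on its geodesic distance from the
    waypoint (bandwidth defaults to the waypoint spacing); the trajectory
    direction at a waypoint is the kernel-weighted least-squares slope of
    the embedding with respect to the geodesic coordinate.
    """
    emb = np.asarray(embedding, dtype=float)
    geo = np.asarray(geodesic, dtype=float)
    vel = np.asarray(velocity_embedded, dtype=float)
    if emb.shape != vel.shape or emb.shape[0] != geo.shape[0]:
        raise ValueError("embedding, geodesic and velocity dimensions must match")
    wp = np.linspace(geo.min(), geo.max(), num_waypoints)
    if bandwidth is None:
        spacing = np.diff(wp)
        bandwidth = float(np.median(spacing)) if spacing.size else 1.0
        bandwidth = max(bandwidth, 1e-9)
    out = np.full(num_waypoints, np.nan)
    for w in range(num_waypoints):
        wts = np.exp(-0.5 * ((geo - wp[w]) / bandwidth) ** 2)
        tot = wts.sum()
        if tot <= 1e-12:
            continue
        v_avg = (vel * wts[:, None]).sum(axis=0) / tot
        g_c = geo - (geo * wts).sum() / tot
        e_c = emb - (emb * wts[:, None]).sum(axis=0) / tot
        denom = (wts * g_c ** 2).sum()
        if denom <= 1e-12:
            continue
        direction = (wts[:, None] * g_c[:, None] * e_c).sum(axis=0) / denom
        nv, nd = np.linalg.norm(v_avg), np.linalg.norm(direction)
        if nv <= 1e-12 or nd <= 1e-12:
            continue
        out[w] = float(v_avg @ direction / (nv * nd))
    return out


def cellwise_auroc_aupr(
    truth: pd.DataFrame,
    pred: pd.DataFrame,
    top_k: int = 10_000,
) -> tuple[float, float, pd.DataFrame]:
    """Mean AUROC / AUPR of per-cell GRN predictions against the binarized
    cell-specific ground truth.

    ``truth`` has columns (cell, regulator, target, active); ``pred`` has
    (cell, regulator, target, score). Per cell, only the ``top_k``
    highest-scoring predictions are retained (unscored ground-truth
    interactions rank at the bottom); cells without positives are excluded
    from the means with a warning.
    """
    for col in ("cell", "regulator", "target"):
        if col not in truth.columns or col not in pred.columns:
            raise ValueError(f"both frames need a {col!r} column")
    pred = pred.sort_values("score", ascending=False).groupby("cell").head(top_k)
    merged = truth.merge(pred, on=["cell", "regulator", "target"], how="left")
    lowest = np.nanmin(merged["score"].to_numpy()) if merged["score"].notna().any() else 0.0
    merged["score"] = merged["score"].fillna(lowest - 1.0)
    rows = []
    skipped = 0
    for cell, grp in merged.groupby("cell"):
        y = grp["active"].to_numpy(dtype=bool)
        s = grp["score"].to_numpy(dtype=float)
        if y.all() or not y.any():
            skipped += 1
            continue
        rows.append(
            {
                "cell": cell,
                "auroc": roc_auc_score(y, s),
                "aupr": average_precision_score(y, s),
            }
        )
    if skipped:
        warnings.warn(f"{skipped} cells without both classes excluded from the means")
    if not rows:
        raise ValueError("no cell had both positive and negative interactions")
    per_cell = pd.DataFrame(rows)
    return float(per_cell.auroc.mean()), float(per_cell.aupr.mean()), per_cell
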