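"""Evaluation metrics: DTW alignment, ABWAP, velocity scores, AUROC/AUPR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochastix.metrics import (
    AlignmentPath,
    abwap,
    cellwise_auroc_aupr,
    dtw_align,
    pca_embedding,
    velocity_arrow_cosine,
    velocity_correlation,
)


def enumerate_monotone_paths(n, m):
    """All valid warping paths on an n x m grid (oracle for small grids)."""
    def extend(path):
        i, j = path[-1]
        if (i, j) == (n - 1, m - 1):
            yield path
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                yield from extend(path + [(i + di, j + dj)])
    yield from extend([(0, 0)])


def path_cost(path, d):
    return sum(d[i, j] for i, j in path)


class TestDtw:
    def test_identical_series_align_diagonally_at_zero_cost(self):
        s = np.array([[0.0], [1.0], [2.0], [3.0]])
        path = dtw_align(s, s)
        assert path.cost == 0.0
        assert path.pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_hand_worked_three_by_two(self):
        # (0,1,2) vs (0,2): optimal cost 1, reached by matching 1 to 0 or 2
        path = dtw_align(np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0]))
        assert path.cost == pytest.approx(1.0)
        assert path.pairs in (
            [(0, 0), (1, 0), (2, 1)],
            [(0, 0), (1, 1), (2, 1)],
        )

    def test_path_satisfies_invariants(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(9, 3))
        path = dtw_align(a, b)
        assert path.validate(6, 9) == []

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_align(np.array([]), np.array([1.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 4), st.integers(2, 4), st.integers(0, 10_000))
    def test_optimal_against_exhaustive_enumeration(self, n, m, seed):
        """DP cost must equal the minimum over all enumerated monotone paths."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, 2))
        b = rng.normal(size=(m, 2))
        d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
        best = min(path_cost(p, d) for p in enumerate_monotone_paths(n, m))
        assert dtw_align(a, b).cost == pytest.approx(best)


class TestAbwap:
    def test_identity_alignment_scores_one(self):
        pt = np.linspace(0, 1, 11)
        path = AlignmentPath([(i, i) for i in range(11)])
        assert abwap(path, pt, pt) == pytest.approx(1.0)

    def test_worst_alignment_scores_zero(self):
        pt = np.linspace(0, 1, 21)
        pairs = [(i, 0) for i in range(21)] + [(20, j) for j in range(1, 21)]
        assert abwap(AlignmentPath(pairs), pt, pt) == pytest.approx(0.0, abs=1e-9)

    def test_hand_worked_three_point_example(self):
        pt = np.array([0.0, 0.5, 1.0])
        path = AlignmentPath([(0, 0), (1, 0), (1, 1), (2, 1), (2, 2)])
        assert abwap(path, pt, pt) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_in_unit_interval_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        pt1 = np.sort(rng.random(n)); pt1[0], pt1[-1] = 0.0, 1.0
        pt2 = np.sort(rng.random(m)); pt2[0], pt2[-1] = 0.0, 1.0
        a = rng.normal(size=(n, 2))
        b = rng.normal(size=(m, 2))
        path = dtw_align(a, b)
        s = abwap(path, pt1, pt2)
        assert -1e-9 <= s <= 1 + 1e-9
        flipped = AlignmentPath([(j, i) for i, j in path.pairs])
        assert abwap(flipped, pt2, pt1) == pytest.approx(s)


class TestVelocityCorrelation:
    def test_perfect_and_inverted_predictions(self):
        gt = np.random.default_rng(1).normal(size=(30, 4))
        assert np.allclose(velocity_correlation(gt, gt), 1.0)
        assert np.allclose(velocity_correlation(gt, -gt), -1.0)

    def test_hand_worked_rank_example(self):
        # ranks (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        gt = np.array([[1.0], [2.0], [3.0], [4.0]])
        pred = np.array([[10.0], [30.0], [20.0], [40.0]])
        assert velocity_correlation(gt, pred)[0] == pytest.approx(0.8)

    def test_zero_variance_gene_is_nan(self):
        gt = np.ones((10, 2))
        gt[:, 1] = np.arange(10)
        pred = np.random.default_rng(2).normal(size=(10, 2))
        rho = velocity_correlation(gt, pred)
        assert np.isnan(rho[0]) and np.isfinite(rho[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            velocity_correlation(np.zeros((3, 2)), np.zeros((2, 3)))


class TestArrowCosine:
    def _setup(self, flip=1.0, rotate=False):
        rng = np.random.default_rng(3)
        geo = np.sort(rng.random(200))
        emb = np.column_stack([geo, geo ** 2])  # smooth curve in 2-D
        direction = np.column_stack([np.ones_like(geo), 2 * geo])
        vel = direction * flip
        if rotate:  # orthogonal field
            vel = np.column_stack([-direction[:, 1], direction[:, 0]])
        return emb, geo, vel

    def test_true_directions_score_one(self):
        emb, geo, vel = self._setup()
        cos = velocity_arrow_cosine(emb, geo, vel, num_waypoints=20)
        assert np.nanmin(cos) > 0.99

    def test_negated_directions_score_minus_one(self):
        emb, geo, vel = self._setup(flip=-1.0)
        cos = velocity_arrow_cosine(emb, geo, vel, num_waypoints=20)
        assert np.nanmax(cos) < -0.99

    def test_orthogonal_directions_score_zero(self):
        emb, geo, vel = self._setup(rotate=True)
        cos = velocity_arrow_cosine(emb, geo, vel, num_waypoints=20)
        assert np.nanmax(np.abs(cos)) < 0.15

    def test_default_waypoint_count(self):
        emb, geo, vel = self._setup()
        assert velocity_arrow_cosine(emb, geo, vel).shape == (100,)

    def test_pca_embedding_is_deterministic(self):
        X = np.random.default_rng(4).normal(size=(50, 10))
        assert np.allclose(pca_embedding(X), pca_embedding(X.copy()))


def _frame(cell, triples):
    return pd.DataFrame(
        [{"cell": cell, "regulator": f"R{i}", "target": f"T{i}", **rest}
         for i, rest in enumerate(triples)]
    )


class TestAurocAupr:
    def test_perfect_ranking(self):
        truth = _frame(0, [{"active": True}, {"active": True}, {"active": False}])
        pred = _frame(0, [{"score": 0.9}, {"score": 0.8}, {"score": 0.1}])
        auroc, aupr, _ = cellwise_auroc_aupr(truth, pred)
        assert auroc == 1.0 and aupr == 1.0

    def test_pair_counting_example(self):
        # positives scored {0.9, 0.4}, negatives {0.6, 0.1}: 3/4 concordant
        truth = _frame(0, [{"active": True}, {"active": True},
                           {"active": False}, {"active": False}])
        pred = _frame(0, [{"score": 0.9}, {"score": 0.4},
                          {"score": 0.6}, {"score": 0.1}])
        auroc, _, _ = cellwise_auroc_aupr(truth, pred)
        assert auroc == pytest.approx(0.75)

    def test_reversed_ranking_scores_zero(self):
        truth = _frame(0, [{"active": True}, {"active": False}])
        pred = _frame(0, [{"score": 0.1}, {"score": 0.9}])
        auroc, _, _ = cellwise_auroc_aupr(truth, pred)
        assert auroc == 0.0

    def test_cells_without_positives_are_excluded(self):
        truth = pd.concat([
            _frame(0, [{"active": True}, {"active": False}]),
            _frame(1, [{"active": False}, {"active": False}]),
        ])
        pred = pd.concat([
            _frame(0, [{"score": 0.9}, {"score": 0.2}]),
            _frame(1, [{"score": 0.5}, {"score": 0.6}]),
        ])
        with pytest.warns(UserWarning, match="excluded"):
            auroc, _, per_cell = cellwise_auroc_aupr(truth, pred)
        assert per_cell.cell.tolist() == [0]

    def test_top_k_filter_drops_low_scores(self):
        truth = _frame(0, [{"active": True}, {"active": False}, {"active": False}])
        pred = _frame(0, [{"score": 0.9}, {"score": 0.8}, {"score": 0.7}])
        full, _, _ = cellwise_auroc_aupr(truth, pred)
        capped, _, _ = cellwise_auroc_aupr(truth, pred, top_k=1)
        assert full == 1.0
        assert capped == 1.0  # unscored negatives rank at the bottom

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auroc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        scores = np.round(rng.random(n), 2)  # encourage ties
        truth = _frame(0, [{"active": bool(l)} for l in labels])
        pred = _frame(0, [{"score": float(s)} for s in scores])
        auroc, _, _ = cellwise_auroc_aupr(truth, pred)
        pos, neg = scores[labels], scores[~labels]
        pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
        assert auroc == pytest.approx(np.mean(pairs))
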