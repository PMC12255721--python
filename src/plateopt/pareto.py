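"""Pareto dominance, hypervolume, and the hypervolume-% benchmark metric.

Everything here uses the maximization convention: an objective vector ``a``
dominates ``b`` iff ``a >= b`` componentwise and ``a > b`` in at least one
coordinate.  Objectives to be minimized (e.g. reaction cost) must be negated
at ingestion.

The hypervolume of a point set relative to a reference point ``r`` is the
Lebesgue measure of the region dominated by the set and bounded below by
``r``.  For two objectives an exact O(n log n) sweep is used; for higher
dimensions an exact recursive slicing over the last objective.  Dominated
points and duplicates never change the value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParetoState",
    "pareto_front",
    "hypervolume",
    "hvi",
    "hypervolume_percent",
    "reference_point",
    "Staircase2D",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 0 if pts.ndim < 2 else pts.shape[-1])
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array (n_points, n_objectives)")
    return pts


def pareto_front(points) -> np.ndarray:
    """Indices of the maximal non-dominated set (duplicates of front points
    are all included)."""
    pts = _as_points(points)
    n = pts.shape[0]
    if n == 0:
        return np.asarray([], dtype=int)
    keep = np.ones(n, dtype=bool)
    # Vectorized pairwise dominance in chunks to bound memory.
    chunk = max(1, int(2**22 // max(1, n)))
    for start in range(0, n, chunk):
        block = pts[start : start + chunk]  # (b, d)
        ge = (pts[None, :, :] >= block[:, None, :]).all(axis=2)  # pts[j] >= block[i]
        gt = (pts[None, :, :] > block[:, None, :]).any(axis=2)
        dominated = (ge & gt).any(axis=1)
        keep[start : start + chunk] = ~dominated
    return np.flatnonzero(keep)


@dataclass
class ParetoState:
    """A point set with its non-dominated front and a reference point."""

    points: np.ndarray
    front: np.ndarray
    reference_point: np.ndarray

    @classmethod
    def from_points(cls, points, reference_point) -> "ParetoState":
        pts = _as_points(points)
        ref = np.asarray(reference_point, dtype=float)
        if pts.size and pts.shape[1] != ref.shape[0]:
            raise ValueError("reference point dimension mismatch")
        return cls(points=pts, front=pareto_front(pts), reference_point=ref)

    @property
    def front_points(self) -> np.ndarray:
        return self.points[self.front]


def _unique_front(pts: np.ndarray) -> np.ndarray:
    """Deduplicated non-dominated points (ties contribute once to HV)."""
    if pts.shape[0] == 0:
        return pts
    front = pts[pareto_front(pts)]
    return np.unique(front, axis=0)


def _hv_2d(front: np.ndarray, ref: np.ndarray) -> float:
    # front: unique non-dominated points; sort descending by first objective,
    # accumulate rectangles against a rising floor on the second.
    order = np.argsort(-front[:, 0], kind="stable")
    f = front[order]
    hv = 0.0
    floor = ref[1]
    for x, y in f:
        if y > floor:
            hv += (x - ref[0]) * (y - floor)
            floor = y
    return hv


def _hv_recursive(front: np.ndarray, ref: np.ndarray) -> float:
    d = front.shape[1]
    if front.shape[0] == 0:
        return 0.0
    if d == 1:
        return float(front[:, 0].max() - ref[0])
    if d == 2:
        return _hv_2d(front, ref)
    # Exact slicing over the last objective: sort descending, each slab
    # between consecutive levels is (level_i - level_{i+1}) thick and its
    # cross-section is the (d-1)-dim HV of the points at or above level_i.
    order = np.argsort(-front[:, -1], kind="stable")
    f = front[order]
    levels = np.append(f[:, -1], ref[-1])
    hv = 0.0
    for i in range(f.shape[0]):
        thickness = levels[i] - levels[i + 1]
        if thickness > 0:
            cross = _unique_front(f[: i + 1, :-1])
            hv += thickness * _hv_recursive(cross, ref[:-1])
    return hv


def hypervolume(points, reference_point) -> float:
    """Exact hypervolume of the region dominated by ``points`` above ``reference_point``.

    Raises if any point lies below the reference point in any coordinate
    (callers must filter such points or lower the reference).
    """
    pts = _as_points(points)
    ref = np.asarray(reference_point, dtype=float)
    if pts.shape[0] == 0:
        return 0.0
    if pts.shape[1] != ref.shape[0]:
        raise ValueError("reference point dimension mismatch")
    if (pts < ref).any():
        raise ValueError("a point lies below the reference point in some coordinate")
    return float(_hv_recursive(_unique_front(pts), ref))


def hvi(candidate_point, state: ParetoState) -> float:
    """Hypervolume improvement of one candidate over the state's front.

    Zero iff the candidate is dominated by (or equal to a member of) the
    front; never negative.
    """
    cand = np.asarray(candidate_point, dtype=float)
    ref = state.reference_point
    if (cand < ref).any():
        raise ValueError("candidate lies below the reference point")
    base = state.front_points
    hv_before = hypervolume(base, ref) if base.shape[0] else 0.0
    pts = np.vstack([base, cand[None, :]]) if base.shape[0] else cand[None, :]
    hv_after = hypervolume(pts, ref)
    return max(0.0, hv_after - hv_before)


def hypervolume_percent(found_points, truth_points, reference_point) -> float:
    """100 x HV(front(found)) / HV(front(truth)) with a shared reference point."""
    found = _as_points(found_points)
    truth = _as_points(truth_points)
    if found.shape[0] == 0 or truth.shape[0] == 0:
        raise ValueError("both point sets must be nonempty")
    ref = np.asarray(reference_point, dtype=float)
    hv_truth = hypervolume(truth, ref)
    if hv_truth == 0.0:
        raise ValueError("truth front has zero hypervolume")
    return 100.0 * hypervolume(found, ref) / hv_truth


def reference_point(points, margin: float = 0.01) -> np.ndarray:
    """Componentwise minimum minus ``margin`` of each objective's range.

    Guarantees the reference is dominated by every point; a degenerate
    objective (zero range) is pushed down by one unit so rectangles stay
    non-degenerate.
    """
    pts = _as_points(points)
    lo = pts.min(axis=0)
    rng = pts.max(axis=0) - lo
    pad = np.where(rng > 0, margin * rng, 1.0)
    return lo - pad


class Staircase2D:
    """Fast vectorized 2-D HVI queries against a fixed front.

    Precomputes the dominance staircase of a front so that the hypervolume
    improvement of many candidate points can be evaluated in O(log k) each.
    Candidates below the reference point are clipped to it (their HVI is 0),
    which is the behaviour acquisition functions need for posterior samples.
    """

    def __init__(self, front_points, reference_point):
        ref = np.asarray(reference_point, dtype=float)
        pts = _as_points(front_points)
        self.ref = ref
        if pts.shape[0]:
            pts = np.maximum(pts, ref)  # clip sampled points into the box
            pts = _unique_front(pts)
            order = np.argsort(pts[:, 0], kind="stable")
            pts = pts[order]  # x ascending -> y strictly descending
        self.front = pts
        k = pts.shape[0]
        # g(u) = height of the staircase at abscissa u (y of the first front
        # point with x >= u); breakpoints at front x's.
        self.xs = pts[:, 0] if k else np.zeros(0)
        self.ys = pts[:, 1] if k else np.zeros(0)
        # cumulative area under the staircase from ref_x to each breakpoint
        if k:
            # column i spans (x_{i-1}, x_i] (x_0 = ref_x) with height y_i
            widths = np.diff(np.concatenate([[ref[0]], self.xs]))
            col_areas = widths * (self.ys - ref[1])
            self.cum_area = np.concatenate([[0.0], np.cumsum(col_areas)])
        else:
            self.cum_area = np.zeros(1)
        self.hv = float(self.cum_area[-1])

    def _area_under(self, px: np.ndarray) -> np.ndarray:
        """Area under the staircase over [ref_x, px] (px clipped to >= ref_x)."""
        if self.front.shape[0] == 0:
            return np.zeros_like(px)
        idx = np.searchsorted(self.xs, px, side="left")  # columns fully inside
        base = self.cum_area[idx]
        # partial strip between the last full column edge and px, whose height
        # is the next column's y (0 past the last breakpoint)
        left = np.where(idx > 0, self.xs[np.maximum(idx - 1, 0)], self.ref[0])
        height = np.where(idx < len(self.ys), np.take(self.ys, np.minimum(idx, len(self.ys) - 1)) - self.ref[1], 0.0)
        return base + np.maximum(px - left, 0.0) * height

    def hvi_many(self, points) -> np.ndarray:
        """HVI of each candidate point over the front (clipped at the reference)."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 1:
            pts = pts[None, :]
        px = np.maximum(pts[:, 0], self.ref[0])
        py = np.maximum(pts[:, 1], self.ref[1])
        rect = (px - self.ref[0]) * (py - self.ref[1])
        if self.front.shape[0] == 0:
            return rect
        # overlap of the candidate rectangle with the staircase region:
        # integral over [ref_x, px] of min(g(u), py) - ref_y.
        # g decreasing => g >= py exactly on [ref_x, u*] where u* is the
        # largest breakpoint x_j with y_j >= py.
        j = np.searchsorted(-self.ys, -py, side="right")  # count of y_i >= py
        ustar = np.where(j > 0, np.take(self.xs, np.maximum(j - 1, 0)), self.ref[0])
        a = np.minimum(px, ustar)
        part1 = (a - self.ref[0]) * (py - self.ref[1])
        part2 = np.maximum(self._area_under(px) - self._area_under(a), 0.0)
        overlap = part1 + part2
        return np.maximum(rect - overlap, 0.0)
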