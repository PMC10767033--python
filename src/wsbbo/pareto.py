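"""Pareto dominance, non-dominated archives, and exact hypervolume (d <= 3).

All objectives are maximized.  A point *a* dominates *b* when a >= b
componentwise with at least one strict inequality.  The hypervolume of a
front relative to a reference point (a per-objective lower bound) is the
Lebesgue measure of the union of boxes [ref, point]; it is computed
exactly by a sweep for up to three objectives, with a seeded Monte-Carlo
estimate beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objectives import ObjectiveVector

__all__ = ["dominates", "hypervolume", "ParetoArchive", "non_dominated_filter"]


def _as_array(v) -> np.ndarray:
    if isinstance(v, ObjectiveVector):
        return v.as_array()
    return np.asarray(v, dtype=float)


def dominates(a, b) -> bool:
    """True iff a >= b componentwise and a > b in at least one component."""
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"dimension mismatch: {av.shape} vs {bv.shape}")
    return bool(np.all(av >= bv) and np.any(av > bv))


def non_dominated_filter(points: np.ndarray) -> np.ndarray:
    """Indices of the non-dominated rows of an (n, d) array (first-seen kept).

    Duplicate objective vectors keep only the first occurrence.
    """
    pts = np.asarray(points, dtype=float)
    keep: list[int] = []
    for i, p in enumerate(pts):
        dominated = False
        for j in keep:
            q = pts[j]
            if np.all(q >= p) and np.any(q > p):
                dominated = True
                break
            if np.array_equal(q, p):
                dominated = True  # duplicate of an archived point
                break
        if dominated:
            continue
        keep = [j for j in keep if not (np.all(p >= pts[j]) and np.any(p > pts[j]))]
        keep.append(i)
    return np.array(keep, dtype=int)


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact 2-d hypervolume of possibly dominated points (union of boxes)."""
    if len(points) == 0:
        return 0.0
    order = np.lexsort((-points[:, 1], -points[:, 0]))  # x desc, y desc
    hv, prev_x, best_y = 0.0, None, ref[1]
    for p in points[order]:
        x, y = p
        if y <= best_y:
            continue
        hv += (x - ref[0]) * (y - best_y)
        best_y = y
    return hv


def _hv3d(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact 3-d hypervolume by sweeping slabs of the third coordinate."""
    if len(points) == 0:
        return 0.0
    zs = np.unique(points[:, 2])
    levels = np.concatenate([[ref[2]], zs])
    hv = 0.0
    for lo, hi in zip(levels[:-1], levels[1:]):
        active = points[points[:, 2] >= hi][:, :2]
        hv += (hi - lo) * _hv2d(active, ref[:2])
    return hv


def hypervolume(front, reference_point, n_mc: int = 1_000_000,
                seed: int = 0) -> float:
    """Dominated hypervolume of *front* relative to *reference_point*.

    Every front point must weakly dominate the reference point (be >= in
    all components with the point != ref).  Exact for d <= 3; for d > 3 a
    seeded Monte-Carlo estimate with *n_mc* samples is returned.
    """
    pts = np.atleast_2d(np.asarray([_as_array(p) for p in front], dtype=float))
    ref = np.asarray(reference_point, dtype=float)
    if pts.size == 0:
        return 0.0
    if pts.shape[1] != ref.shape[0]:
        raise ValueError("front/reference dimension mismatch")
    bad = np.any(pts < ref, axis=1)
    if np.any(bad):
        raise ValueError(
            f"front point {pts[bad][0]} does not dominate reference {ref}"
        )
    d = pts.shape[1]
    if d == 1:
        return float(pts[:, 0].max() - ref[0])
    if d == 2:
        return float(_hv2d(pts, ref))
    if d == 3:
        return float(_hv3d(pts, ref))
    # Monte-Carlo fallback: sample the bounding box, count dominated points.
    rng = np.random.default_rng(seed)
    upper = pts.max(axis=0)
    box = np.prod(upper - ref)
    if box == 0:
        return 0.0
    samples = rng.uniform(ref, upper, size=(n_mc, d))
    hit = np.zeros(n_mc, dtype=bool)
    for p in pts:
        hit |= np.all(samples <= p, axis=1)
    return float(box * hit.mean())


@dataclass
class ParetoArchive:
    """Incrementally maintained non-dominated set with progress traces.

    ``reference_point`` is fixed at construction; hypervolume history and
    per-objective best-so-far traces are appended at every insertion
    attempt, so both are non-decreasing over a run.  Points falling below
    the reference in some component are clipped to it for hypervolume
    accounting only (their stored coordinates are untouched).

    ``objective_scale`` divides each (point - reference) coordinate before
    hypervolume computation, so objectives measured on very different
    scales contribute comparably; dominance and the stored entries are
    unaffected.
    """

    reference_point: np.ndarray
    entries: list[tuple[str, np.ndarray]] = field(default_factory=list)
    hv_history: list[tuple[int, float]] = field(default_factory=list)
    best_so_far: list[np.ndarray] = field(default_factory=list)
    duplicates: list[tuple[str, np.ndarray]] = field(default_factory=list)
    objective_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reference_point = np.asarray(self.reference_point, dtype=float)
        if self.objective_scale is not None:
            self.objective_scale = np.asarray(self.objective_scale, dtype=float)
            if np.any(self.objective_scale <= 0):
                raise ValueError("objective_scale must be positive")

    @property
    def front(self) -> np.ndarray:
        if not self.entries:
            return np.zeros((0, len(self.reference_point)))
        return np.stack([v for _, v in self.entries])

    def _clipped_front(self, extra: np.ndarray | None = None) -> np.ndarray:
        pts = self.front
        if extra is not None:
            pts = np.vstack([pts, extra[None, :]]) if pts.size else extra[None, :]
        return np.maximum(pts, self.reference_point)

    def _hv(self, pts: np.ndarray) -> float:
        shifted = pts - self.reference_point
        if self.objective_scale is not None:
            shifted = shifted / self.objective_scale
        return hypervolume(shifted, np.zeros(len(self.reference_point)))

    def hypervolume(self) -> float:
        if not self.entries:
            return 0.0
        return self._hv(self._clipped_front())

    def hypervolume_with(self, vector) -> float:
        """Hypervolume of the front augmented by one candidate point."""
        v = _as_array(vector)
        return self._hv(self._clipped_front(v))

    def update(self, sequence: str, vector, index: int | None = None) -> bool:
        """Insert a candidate; returns True if it joined the front.

        Dominated candidates and duplicate objective vectors leave the
        front unchanged (duplicates are kept in a side list).  Entries
        dominated by the candidate are removed.
        """
        v = _as_array(vector)
        inserted = False
        duplicate = any(np.array_equal(v, w) for _, w in self.entries)
        if duplicate:
            self.duplicates.append((sequence, v))
        elif not any(dominates(w, v) for _, w in self.entries):
            self.entries = [(s, w) for s, w in self.entries if not dominates(v, w)]
            self.entries.append((sequence, v))
            inserted = True
        if index is None:
            index = len(self.hv_history)
        if self.best_so_far:
            self.best_so_far.append(np.maximum(self.best_so_far[-1], v))
        else:
            self.best_so_far.append(v.copy())
        self.hv_history.append((index, self.hypervolume()))
        return inserted

    def to_frame(self):
        import pandas as pd

        cols = ["f_mean", "f_stab", "f_sol"][: len(self.reference_point)]
        rows = [
            {"sequence": s, **dict(zip(cols, v))} for s, v in self.entries
        ]
        return pd.DataFrame(rows, columns=["sequence", *cols])
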