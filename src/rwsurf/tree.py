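"""Single survival decision tree: the base learner of the weighted forest.

Trees are grown on right-censored data with the log-rank splitting rule and
store a Nelson--Aalen cumulative hazard function (CHF) in each leaf. At
every internal node ``mtry`` features are sampled without replacement and,
for each, a set of candidate thresholds drawn from the in-node values is
scored by the standardized two-sample log-rank statistic; the admissible
split with the largest statistic wins. Records with ``x <= threshold`` go
left. Growth stops at ``max_depth``, when a node holds fewer than
``2 * min_leaf_events`` events, or when no split leaves at least
``min_leaf_events`` events on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalData

__all__ = [
    "StepCHF",
    "nelson_aalen",
    "logrank_statistic",
    "SurvivalTree",
    "grow_tree",
    "predict_tree_chf",
]


@dataclass
class StepCHF:
    """Right-continuous step cumulative hazard on an increasing time grid.

    ``H(t)`` equals the value at the largest grid time ``<= t`` and 0 for
    ``t`` below the grid. Values are non-negative and non-decreasing.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.size and (self.values[0] < 0 or np.any(np.diff(self.values) < -1e-12)):
            raise ValueError("values must be non-negative and non-decreasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)] if self.values.size else 0.0, 0.0)
        return out if out.ndim else float(out)


def nelson_aalen(time, event) -> StepCHF:
    """Nelson--Aalen estimator of the cumulative hazard.

    At each distinct event time ``t`` the hazard increments by ``d(t)/Y(t)``
    with ``d`` the number of events at ``t`` and ``Y`` the at-risk count
    (subjects with follow-up ``>= t``; censorings at ``t`` count as at
    risk). With no events the CHF is identically zero on an empty grid.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("at least one record is required")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ut, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), first)
    at_risk = len(t) - first
    mask = d > 0
    if not mask.any():
        return StepCHF(np.empty(0), np.empty(0))
    return StepCHF(ut[mask], np.cumsum(d[mask] / at_risk[mask]))


def _logrank_for_thresholds(t_sorted, e_sorted, v_sorted, thresholds, min_leaf_events):
    """Standardized log-rank statistic for every candidate threshold.

    ``t_sorted``/``e_sorted``/``v_sorted`` are the node's times, events and
    one feature column, jointly sorted by time ascending. Group 1 ("left")
    is ``v <= threshold``. Returns an array of |O-E|/sqrt(V), with -inf for
    candidates leaving fewer than ``min_leaf_events`` events (or zero
    members) on either side, and 0 where the variance vanishes.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    m = len(t_sorted)
    M = v_sorted[:, None] <= thresholds[None, :]  # membership of group 1

    ut, first = np.unique(t_sorted, return_index=True)
    suffix = np.cumsum(M[::-1], axis=0)[::-1]  # at-risk counts from each row down
    Y1 = suffix[first]  # (u, k)
    Y = (m - first).astype(float)
    e_col = e_sorted.astype(float)
    d = np.add.reduceat(e_col, first)
    d1 = np.add.reduceat(M * e_col[:, None], first, axis=0)

    ev = d > 0
    Yv, dv = Y[ev], d[ev]
    frac = Y1[ev] / Yv[:, None]
    o_minus_e = (d1[ev] - dv[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hyper = np.where(Yv > 1, dv * (Yv - dv) / (Yv - 1), 0.0)
    var = (hyper[:, None] * frac * (1.0 - frac)).sum(axis=0)
    stat = np.where(var > 0, np.abs(o_minus_e) / np.sqrt(np.maximum(var, 1e-300)), 0.0)

    left_events = (M * e_col[:, None]).sum(axis=0)
    total_events = e_col.sum()
    left_n = M.sum(axis=0)
    admissible = (
        (left_n > 0)
        & (left_n < m)
        & (left_events >= min_leaf_events)
        & (total_events - left_events >= min_leaf_events)
    )
    return np.where(admissible, stat, -np.inf)


def logrank_statistic(time_a, event_a, time_b, event_b) -> float:
    """Absolute standardized two-sample log-rank statistic.

    Zero when the variance term vanishes (e.g. no events, or the groups are
    indistinguishable at every event time).
    """
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([time_a, time_b])
    e = np.concatenate([np.asarray(event_a), np.asarray(event_b)])
    g = np.concatenate([np.zeros(time_a.size), np.ones(time_b.size)])
    order = np.argsort(t, kind="stable")
    stat = _logrank_for_thresholds(t[order], e[order], g[order], np.array([0.5]), 0)[0]
    return float(max(stat, 0.0))  # -inf only if a group were empty


@dataclass
class _Leaf:
    chf: StepCHF
    count: int
    depth: int
    leaf_id: int


@dataclass
class _Split:
    feature: int
    threshold: float
    depth: int
    left: object
    right: object


@dataclass
class SurvivalTree:
    """Fitted survival tree with a shared event-time grid.

    ``grid`` holds the distinct event times of the training sample; leaf
    CHFs are re-sampled onto it at prediction time.
    """

    root: object
    grid: np.ndarray
    n_features: int
    leaves: list = field(default_factory=list)

    @property
    def max_depth_realized(self) -> int:
        return max((lf.depth for lf in self.leaves), default=0)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for every row of ``X`` (ties at a threshold route left)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(len(X), dtype=int)

        def recurse(node, idx):
            if isinstance(node, _Leaf):
                out[idx] = node.leaf_id
                return
            mask = X[idx, node.feature] <= node.threshold
            recurse(node.left, idx[mask])
            recurse(node.right, idx[~mask])

        recurse(self.root, np.arange(len(X)))
        return out

    def leaf_values_on(self, times: np.ndarray) -> np.ndarray:
        """Matrix (n_leaves, len(times)) of leaf CHFs evaluated on ``times``."""
        return np.vstack([lf.chf(times) for lf in self.leaves]) if self.leaves else np.empty((0, len(times)))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node):
            if isinstance(node, _Leaf):
                return {
                    "leaf": True,
                    "times": node.chf.times.tolist(),
                    "values": node.chf.values.tolist(),
                    "count": node.count,
                    "depth": node.depth,
                }
            return {
                "leaf": False,
                "feature": int(node.feature),
                "threshold": float(node.threshold),
                "depth": node.depth,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {"grid": self.grid.tolist(), "n_features": self.n_features, "root": enc(self.root)}

    @classmethod
    def from_dict(cls, payload: dict) -> "SurvivalTree":
        leaves: list[_Leaf] = []

        def dec(node):
            if node["leaf"]:
                lf = _Leaf(
                    chf=StepCHF(np.asarray(node["times"]), np.asarray(node["values"])),
                    count=int(node["count"]),
                    depth=int(node["depth"]),
                    leaf_id=len(leaves),
                )
                leaves.append(lf)
                return lf
            return _Split(
                feature=node["feature"],
                threshold=node["threshold"],
                depth=node["depth"],
                left=dec(node["left"]),
                right=dec(node["right"]),
            )

        root = dec(payload["root"])
        return cls(root=root, grid=np.asarray(payload["grid"], dtype=float), n_features=int(payload["n_features"]), leaves=leaves)


def grow_tree(
    data: SurvivalData,
    *,
    mtry: int | None = None,
    min_leaf_events: int = 3,
    max_depth: int = 20,
    n_split_candidates: int = 10,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> SurvivalTree:
    """Grow a log-rank survival tree on ``data``.

    ``mtry`` defaults to ``ceil(sqrt(p))``. With ``exhaustive=True`` every
    unique in-node value (except the maximum) of every sampled feature is
    scored — used by oracle tests against brute-force split search; the
    default draws at most ``n_split_candidates`` thresholds per feature.
    Degenerate inputs yield a single-leaf tree. Deterministic for a seeded
    ``rng``.
    """
    if len(data) == 0:
        raise ValueError("cannot grow a tree on an empty dataset")
    p = data.n_features
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if mtry > p:
        raise ValueError("mtry exceeds the number of features")
    rng = rng if rng is not None else np.random.default_rng()
    X, time, event = data.X, data.time, data.event
    leaves: list[_Leaf] = []

    def make_leaf(idx, depth):
        lf = _Leaf(chf=nelson_aalen(time[idx], event[idx]), count=len(idx), depth=depth, leaf_id=len(leaves))
        leaves.append(lf)
        return lf

    def build(idx, depth):
        n_events = int(event[idx].sum())
        if depth >= max_depth or n_events < 2 * min_leaf_events:
            return make_leaf(idx, depth)
        order = np.argsort(time[idx], kind="stable")
        ts, es = time[idx][order], event[idx][order]
        feats = np.sort(rng.choice(p, size=mtry, replace=False))
        best_stat, best_feat, best_thr = 0.0, None, None
        for f in feats:
            v = X[idx, f]
            uniq = np.unique(v)
            if uniq.size < 2:
                continue
            cands = uniq[:-1]
            if not exhaustive and cands.size > n_split_candidates:
                cands = np.sort(rng.choice(cands, size=n_split_candidates, replace=False))
            stats = _logrank_for_thresholds(ts, es, v[order], cands, min_leaf_events)
            j = int(np.argmax(stats))
            if stats[j] > best_stat:
                best_stat, best_feat, best_thr = float(stats[j]), int(f), float(cands[j])
        if best_feat is None:
            return make_leaf(idx, depth)
        mask = X[idx, best_feat] <= best_thr
        return _Split(
            feature=best_feat,
            threshold=best_thr,
            depth=depth,
            left=build(idx[mask], depth + 1),
            right=build(idx[~mask], depth + 1),
        )

    root = build(np.arange(len(data)), 0)
    grid = np.unique(time[event == 1])
    return SurvivalTree(root=root, grid=grid, n_features=p, leaves=leaves)


def predict_tree_chf(tree: SurvivalTree, x) -> StepCHF:
    """Route ``x`` to its leaf and return the leaf CHF on the tree's grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != tree.n_features:
        raise ValueError("feature vector length must match the training features")
    leaf = tree.leaves[tree.apply(x[None, :])[0]]
    return StepCHF(tree.grid.copy(), leaf.chf(tree.grid))
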