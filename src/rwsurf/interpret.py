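"""Interpretability outputs: permutation importance, minimal depth, rules.

Permutation variable importance (VIMP) measures the increase in
out-of-bag squared prediction error when one feature's values are
shuffled across records. The error is a fixed-horizon squared loss
between the predicted event probability ``1 - S_w(horizon | x)`` and the
observed status at the horizon, restricted to records whose status at
the horizon is determinable (event before it, or followed past it);
each record is predicted only by the trees for which it is out-of-bag,
with the forest's weights renormalized over those trees.

Minimal depth is a structure-only statistic: the depth of a feature's
first split, averaged over trees; features a tree never uses contribute
that tree's maximum depth + 1. Smaller is more important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalData
from .forest import ForestModel
from .tree import _Leaf, _Split

__all__ = [
    "ImportanceReport",
    "DecisionRule",
    "permutation_importance",
    "minimal_depth",
    "importance_report",
    "extract_rules",
    "oob_mortality",
    "plot_importance",
]


@dataclass
class ImportanceReport:
    """Per-feature VIMP and minimal depth with ranks (1 = most important)."""

    table: pd.DataFrame  # index: feature; columns: vimp, minimal_depth, vimp_rank, depth_rank

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def _oob_weight_matrix(forest: ForestModel) -> np.ndarray:
    """(n_train, B) weights restricted to each record's OOB trees, renormalized."""
    W = forest.oob_mask().astype(float) * forest.weights[None, :]
    totals = W.sum(axis=1, keepdims=True)
    covered = totals[:, 0] > 0
    if not covered.all():
        warnings.warn("some records are in-bag for every tree; they are excluded from OOB error")
    W[covered] = W[covered] / totals[covered]
    W[~covered] = 0.0
    return W


def _horizon_hazard(forest: ForestModel, X: np.ndarray, horizon: float, W: np.ndarray) -> np.ndarray:
    """OOB-weighted ensemble CHF at ``horizon`` for every record."""
    pos = int(np.searchsorted(forest.grid, horizon, side="right")) - 1
    H = np.zeros(len(X))
    if pos < 0:
        return H
    for b, tree in enumerate(forest.trees):
        col = W[:, b]
        if not col.any():
            continue
        H += col * forest.leaf_table(b)[tree.apply(X), pos]
    return H


def _oob_event_prob(forest: ForestModel, X: np.ndarray, horizon: float, W: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-_horizon_hazard(forest, X, horizon, W))


def oob_mortality(forest: ForestModel, data: SurvivalData) -> np.ndarray:
    """Out-of-bag mortality score (CHF summed over the grid) per record.

    Each training record is scored only by trees that did not see it,
    with the forest weights renormalized over those trees. Records that
    are in-bag everywhere get NaN.
    """
    if len(data) != forest.n_train:
        raise ValueError("OOB scores are defined for the training records")
    W = _oob_weight_matrix(forest)
    out = np.zeros(len(data))
    for b, tree in enumerate(forest.trees):
        col = W[:, b]
        if not col.any():
            continue
        out += col * forest.leaf_table(b)[tree.apply(data.X)].sum(axis=1)
    out[W.sum(axis=1) == 0] = np.nan
    return out


def permutation_importance(forest: ForestModel, data: SurvivalData,
                           horizon: float | None = None, seed: int = 0) -> pd.Series:
    """Out-of-bag permutation importance of every feature.

    Returns ``permuted error - baseline error`` per feature (positive =
    predictive). Default horizon is the median follow-up time.
    Deterministic for a fixed seed; a feature constant across records has
    importance exactly zero.
    """
    if len(data) != forest.n_train:
        raise ValueError("permutation importance requires the training records")
    if horizon is None:
        horizon = float(np.median(data.time))
    W = _oob_weight_matrix(forest)
    covered = W.sum(axis=1) > 0
    determinable = ((data.event == 1) & (data.time <= horizon)) | (data.time >= horizon)
    use = covered & determinable
    if not use.any():
        raise ValueError("no OOB record has a determinable status at the horizon")
    status = ((data.event == 1) & (data.time <= horizon)).astype(float)

    def error(X):
        p = _oob_event_prob(forest, X, horizon, W)
        return float(np.mean((p[use] - status[use]) ** 2))

    base_err = error(data.X)
    rng = np.random.default_rng(seed)
    n = len(data)
    out = {}
    for j, name in enumerate(forest.feature_names):
        col = data.X[:, j]
        if np.unique(col).size == 1:
            warnings.warn(f"feature {name!r} is constant; importance is 0 by construction")
            out[name] = 0.0
            continue
        perm = rng.permutation(n)
        Xp = data.X.copy()
        Xp[:, j] = col[perm]
        out[name] = error(Xp) - base_err
    return pd.Series(out, name="vimp")


def minimal_depth(forest: ForestModel) -> pd.Series:
    """Mean depth of each feature's first split across trees.

    Unused features contribute ``max realized depth + 1`` for that tree;
    the statistic depends only on tree structure, never on the weights.
    """
    p = len(forest.feature_names)
    totals = np.zeros(p)
    for tree in forest.trees:
        first = np.full(p, np.inf)

        def visit(node):
            if isinstance(node, _Leaf):
                return
            first[node.feature] = min(first[node.feature], node.depth)
            visit(node.left)
            visit(node.right)

        visit(tree.root)
        fallback = tree.max_depth_realized + 1
        totals += np.where(np.isfinite(first), first, fallback)
    return pd.Series(totals / forest.n_trees, index=forest.feature_names, name="minimal_depth")


def importance_report(forest: ForestModel, data: SurvivalData,
                      horizon: float | None = None, seed: int = 0) -> ImportanceReport:
    """Combine VIMP and minimal depth into one ranked table."""
    vimp = permutation_importance(forest, data, horizon=horizon, seed=seed)
    depth = minimal_depth(forest)
    table = pd.DataFrame({"vimp": vimp, "minimal_depth": depth})
    table["vimp_rank"] = table["vimp"].rank(ascending=False, method="first").astype(int)
    table["depth_rank"] = table["minimal_depth"].rank(ascending=True, method="first").astype(int)
    return ImportanceReport(table=table)


@dataclass
class DecisionRule:
    """Conjunctive root-to-leaf rule of the main (highest-weight) tree."""

    conditions: list[tuple[str, str, float]]  # (feature, "<=" or ">", threshold)
    n_oob: int
    event_fraction_oob: float
    mortality: float  # leaf CHF summed over the tree grid

    def __str__(self) -> str:
        if not self.conditions:
            cond = "(all patients)"
        else:
            cond = " AND ".join(f"{f} {op} {thr:.4g}" for f, op, thr in self.conditions)
        return f"IF {cond} THEN mortality={self.mortality:.3f} (OOB n={self.n_oob}, events={self.event_fraction_oob:.2f})"


def _simplify(conditions):
    """Keep only the binding bound per feature/direction (consistent interval)."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order = []
    for f, op, thr in conditions:
        if op == "<=":
            if f not in upper or thr < upper[f]:
                upper[f] = thr
        else:
            if f not in lower or thr > lower[f]:
                lower[f] = thr
        if f not in order:
            order.append(f)
    out = []
    for f in order:
        if f in lower:
            out.append((f, ">", lower[f]))
        if f in upper:
            out.append((f, "<=", upper[f]))
    return out


def extract_rules(forest: ForestModel, top_k: int, data: SurvivalData | None = None) -> list[DecisionRule]:
    """Top-k highest-mortality leaf rules of the highest-weight tree.

    Leaf statistics (member count, event fraction) are computed on the
    out-of-bag records of that tree when training ``data`` is supplied.
    ``top_k`` beyond the leaf count returns every leaf; ``top_k = 0``
    returns an empty list.
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    b = int(np.argmax(forest.weights))
    tree = forest.trees[b]
    names = forest.feature_names

    paths: dict[int, list] = {}

    def walk(node, conds):
        if isinstance(node, _Leaf):
            paths[node.leaf_id] = conds
            return
        walk(node.left, conds + [(names[node.feature], "<=", node.threshold)])
        walk(node.right, conds + [(names[node.feature], ">", node.threshold)])

    walk(tree.root, [])
    mortality = forest.leaf_table(b).sum(axis=1)

    oob_leaf = oob_event = None
    if data is not None:
        oob = np.ones(len(data), dtype=bool)
        oob[np.unique(forest.inbag[b])] = False
        leaf_ids = tree.apply(data.X[oob])
        oob_leaf = leaf_ids
        oob_event = data.event[oob]

    ranked = np.argsort(-mortality, kind="stable")[: min(top_k, len(mortality))]
    rules = []
    for leaf_id in ranked:
        if oob_leaf is not None:
            members = oob_leaf == leaf_id
            n_oob = int(members.sum())
            frac = float(oob_event[members].mean()) if n_oob else float("nan")
        else:
            n_oob, frac = 0, float("nan")
        rules.append(DecisionRule(
            conditions=_simplify(paths[int(leaf_id)]),
            n_oob=n_oob,
            event_fraction_oob=frac,
            mortality=float(mortality[leaf_id]),
        ))
    return rules


def plot_importance(report: ImportanceReport, path=None):
    """Horizontal bar charts of VIMP and minimal depth (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.table.sort_values("vimp")
    fig, axes = plt.subplots(1, 2, figsize=(10, max(3, 0.3 * len(table))))
    axes[0].barh(table.index, table["vimp"], color="steelblue")
    axes[0].set_title("Permutation importance")
    depth = report.table.sort_values("minimal_depth", ascending=False)
    axes[1].barh(depth.index, depth["minimal_depth"], color="darkorange")
    axes[1].set_title("Minimal depth")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
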