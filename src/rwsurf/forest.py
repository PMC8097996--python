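"""Bootstrap ensemble of survival trees with learned, L2-regularized weights.

A plain random survival forest averages the per-tree cumulative hazards
with equal weights 1/B. Here the ensemble CHF is a convex combination

    H_w(t | x) = sum_b w_b * H_b(t | x),   w on the probability simplex,

and the weights are learned by minimizing a discrete-hazard negative
log-likelihood plus an L2 penalty ``lambda * sum w_b^2``, with the penalty
strength chosen by k-fold cross-validation on the training records.
Constraining the weights to the simplex keeps the ensemble CHF a valid
(non-decreasing, non-negative) cumulative hazard.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalData
from .tree import StepCHF, SurvivalTree, grow_tree

__all__ = [
    "ForestModel",
    "RiskPrediction",
    "RWRSFConfig",
    "fit_forest",
    "predict",
    "ensemble_negloglik",
    "learn_weights",
    "select_lambda",
    "fit_rwrsf",
]

_EPS = 1e-12  # floor inside the log of the event term
_SIMPLEX_TOL = 1e-8

DEFAULT_LAMBDA_GRID = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0)


@dataclass
class RWRSFConfig:
    """Hyperparameters of the regularized weighted forest.

    ``lambda_reg`` forces a fixed regularization strength and skips
    cross-validated selection; ``loss`` chooses between the default
    discrete-hazard likelihood and a Cox partial-likelihood alternative
    over the scalar mortality score.
    """

    n_trees: int = 100
    mtry: int | None = None
    min_leaf_events: int = 3
    max_depth: int = 20
    n_split_candidates: int = 10
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    cv_folds: int = 5
    lambda_reg: float | None = None
    loss: str = "hazard"
    seed: int = 0


@dataclass
class ForestModel:
    """Fitted forest: trees, bootstrap bookkeeping, weights and grid."""

    trees: list[SurvivalTree]
    inbag: list[np.ndarray]
    weights: np.ndarray
    lambda_reg: float
    grid: np.ndarray
    feature_names: list[str]
    n_train: int
    seed: int
    params: dict = field(default_factory=dict)
    _leaf_tables: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def leaf_table(self, b: int) -> np.ndarray:
        """Cached (n_leaves, len(grid)) CHF matrix for tree ``b``."""
        if not self._leaf_tables:
            self._leaf_tables = [t.leaf_values_on(self.grid) for t in self.trees]
        return self._leaf_tables[b]

    def oob_mask(self) -> np.ndarray:
        """(n_train, B) boolean: True where a training row is out-of-bag."""
        mask = np.ones((self.n_train, self.n_trees), dtype=bool)
        for b, idx in enumerate(self.inbag):
            mask[np.unique(idx), b] = False
        return mask

    # -- persistence ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "trees": [t.to_dict() for t in self.trees],
            "inbag": [idx.tolist() for idx in self.inbag],
            "weights": self.weights.tolist(),
            "lambda_reg": self.lambda_reg,
            "grid": self.grid.tolist(),
            "feature_names": self.feature_names,
            "n_train": self.n_train,
            "seed": self.seed,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ForestModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            trees=[SurvivalTree.from_dict(t) for t in payload["trees"]],
            inbag=[np.asarray(i, dtype=int) for i in payload["inbag"]],
            weights=np.asarray(payload["weights"], dtype=float),
            lambda_reg=float(payload["lambda_reg"]),
            grid=np.asarray(payload["grid"], dtype=float),
            feature_names=list(payload["feature_names"]),
            n_train=int(payload["n_train"]),
            seed=int(payload["seed"]),
            params=dict(payload["params"]),
        )


@dataclass
class RiskPrediction:
    """Ensemble prediction: CHF on the global grid, survival, mortality.

    ``mortality`` is the sum of the ensemble CHF over the grid times — the
    scalar risk score used for ranking patients.
    """

    grid: np.ndarray
    chf: np.ndarray  # (n, T)
    mortality: np.ndarray  # (n,)
    survival: np.ndarray  # (n, T)

    def chf_for(self, i: int) -> StepCHF:
        return StepCHF(self.grid.copy(), self.chf[i])


def fit_forest(data: SurvivalData, n_trees: int = 100, *, mtry=None, min_leaf_events=3,
               max_depth=20, n_split_candidates=10, seed: int = 0) -> ForestModel:
    """Fit a plain (uniform-weight) random survival forest.

    Each tree is grown on a bootstrap sample of ``n`` draws with
    replacement; out-of-bag membership is recorded. Weights start uniform
    and stay so until :func:`learn_weights`. Deterministic for a fixed
    seed.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n = len(data)
    children = np.random.SeedSequence(seed).spawn(n_trees)
    trees, inbag = [], []
    for b in range(n_trees):
        rng = np.random.default_rng(children[b])
        idx = rng.integers(0, n, n)
        tree = grow_tree(
            data.subset(idx),
            mtry=mtry,
            min_leaf_events=min_leaf_events,
            max_depth=max_depth,
            n_split_candidates=n_split_candidates,
            rng=rng,
        )
        trees.append(tree)
        inbag.append(idx)
    grid = np.unique(data.time[data.event == 1])
    return ForestModel(
        trees=trees,
        inbag=inbag,
        weights=np.full(n_trees, 1.0 / n_trees),
        lambda_reg=0.0,
        grid=grid,
        feature_names=list(data.feature_names),
        n_train=n,
        seed=seed,
        params={
            "n_trees": n_trees,
            "mtry": mtry,
            "min_leaf_events": min_leaf_events,
            "max_depth": max_depth,
            "n_split_candidates": n_split_candidates,
        },
    )


def predict(forest: ForestModel, X, weights=None) -> RiskPrediction:
    """Weighted ensemble prediction for one vector or a matrix of rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(forest.feature_names):
        raise ValueError("feature vector length must match the training features")
    w = forest.weights if weights is None else np.asarray(weights, dtype=float)
    _check_simplex(w, forest.n_trees)
    H = np.zeros((len(X), len(forest.grid)))
    for b, tree in enumerate(forest.trees):
        if w[b] == 0.0:
            continue
        H += w[b] * forest.leaf_table(b)[tree.apply(X)]
    return RiskPrediction(grid=forest.grid, chf=H, mortality=H.sum(axis=1), survival=np.exp(-H))


def _check_simplex(w: np.ndarray, B: int) -> None:
    if w.shape != (B,):
        raise ValueError("weights length must equal the number of trees")
    if np.any(w < -_SIMPLEX_TOL) or abs(w.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError("weights must lie on the probability simplex")


def _likelihood_arrays(forest: ForestModel, data: SurvivalData):
    """Per-record, per-tree hazard levels and increments at the record's time.

    Returns ``A[i, b] = H_b(t_i | x_i)`` and ``D[i, b]`` = increment of
    ``H_b`` at the largest global grid time ``<= t_i`` (0 if ``t_i``
    precedes the grid). The ensemble level/increment is then ``A @ w`` /
    ``D @ w``.
    """
    grid = forest.grid
    n, B = len(data), forest.n_trees
    A = np.zeros((n, B))
    D = np.zeros((n, B))
    if grid.size == 0:
        return A, D
    pos = np.searchsorted(grid, data.time, side="right") - 1
    has = pos >= 0
    prev = pos - 1
    for b, tree in enumerate(forest.trees):
        L = forest.leaf_table(b)
        rows = L[tree.apply(data.X)]
        A[has, b] = rows[has, pos[has]]
        with_prev = pos >= 1
        D[:, b] = np.where(has, A[:, b] - np.where(with_prev, rows[np.arange(n), np.clip(prev, 0, None)], 0.0), 0.0)
    return A, D


def _negloglik(A, D, event, w) -> float:
    Hw = A @ w
    dHw = D @ w
    ll = -event * np.log(dHw + _EPS) + Hw
    return float(ll.mean())


def _negloglik_grad(A, D, event, w) -> np.ndarray:
    dHw = D @ w
    return (-(D * (event / (dHw + _EPS))[:, None]) + A).mean(axis=0)


def _cox_negloglik_and_grad(M, time, event, w):
    """Cox partial likelihood (Breslow) over mortality scores ``M @ w``."""
    s = M @ w
    n = len(time)
    order = np.argsort(-time, kind="stable")  # decreasing time: risk sets are prefixes
    ts = time[order]
    es = np.exp(s[order] - s.max())
    cum = np.cumsum(es)
    cum_m = np.cumsum(es[:, None] * M[order], axis=0)
    # risk set of an event at t = all records with time >= t (tie-inclusive)
    asc = ts[::-1]
    ev = event[order] == 1
    last = n - np.searchsorted(asc, ts[ev], side="left") - 1
    loss = -(s[order][ev] - s.max() - np.log(cum[last])).sum() / n
    grad = -(M[order][ev] - cum_m[last] / cum[last][:, None]).sum(axis=0) / n
    return float(loss), grad


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort algorithm)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > (css - 1.0))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def ensemble_negloglik(forest: ForestModel, data: SurvivalData, weights) -> float:
    """Mean discrete-hazard negative log-likelihood of ``weights``.

    Per record: ``-event * log(dH_w(t_i|x_i) + eps) + H_w(t_i|x_i)`` with
    ``eps = 1e-12`` guarding zero increments.
    """
    w = np.asarray(weights, dtype=float)
    _check_simplex(w, forest.n_trees)
    A, D = _likelihood_arrays(forest, data)
    return _negloglik(A, D, data.event.astype(float), w)


def _optimize_weights(objective, B, tol=1e-6, max_iter=500):
    """Projected gradient descent on the simplex from the uniform start.

    ``objective(w)`` returns (value, gradient). Backtracking line search
    guarantees the penalized objective never increases; stops when the
    unit-step projected-gradient displacement falls below ``tol``.
    """
    w = np.full(B, 1.0 / B)
    f, g = objective(w)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite loss at the uniform start")
    step = 1.0
    for _ in range(max_iter):
        if np.linalg.norm(project_simplex(w - g) - w) < tol:
            break
        accepted = False
        for _ in range(60):
            w_new = project_simplex(w - step * g)
            f_new, g_new = objective(w_new)
            if np.isfinite(f_new) and f_new <= f - 1e-4 * np.dot(g, w - w_new) + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted or np.allclose(w_new, w):
            break
        w, f, g = w_new, f_new, g_new
        step = min(step * 2.0, 1e6)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite loss during weight optimization")
    return w


def learn_weights(forest: ForestModel, data: SurvivalData, lambda_reg: float,
                  *, loss: str = "hazard", tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Learn simplex tree weights minimizing loss + ``lambda_reg * ||w||^2``.

    The achieved penalized objective never exceeds its value at the
    uniform start (monotone projected-gradient descent).
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    B = forest.n_trees
    if loss == "hazard":
        A, D = _likelihood_arrays(forest, data)
        ev = data.event.astype(float)

        def objective(w):
            return (
                _negloglik(A, D, ev, w) + lambda_reg * float(w @ w),
                _negloglik_grad(A, D, ev, w) + 2.0 * lambda_reg * w,
            )

    elif loss == "cox":
        M = np.stack(
            [forest.leaf_table(b)[tree.apply(data.X)].sum(axis=1) for b, tree in enumerate(forest.trees)],
            axis=1,
        )

        def objective(w):
            f, g = _cox_negloglik_and_grad(M, data.time, data.event, w)
            return f + lambda_reg * float(w @ w), g + 2.0 * lambda_reg * w

    else:
        raise ValueError(f"unknown loss {loss!r}")
    return _optimize_weights(objective, B, tol=tol, max_iter=max_iter)


def select_lambda(forest: ForestModel, data: SurvivalData, lambda_grid=DEFAULT_LAMBDA_GRID,
                  n_folds: int = 5, seed: int = 0, loss: str = "hazard") -> float:
    """Choose the L2 strength by k-fold CV of the unpenalized held-out loss.

    For each candidate the weights are learned on k-1 folds and scored on
    the held-out fold; the candidate with the smallest mean held-out loss
    wins, ties going to the larger (more regularized) value.
    """
    lambda_grid = sorted(set(float(v) for v in lambda_grid))
    if not lambda_grid:
        raise ValueError("lambda_grid must be non-empty")
    n = len(data)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    A, D = _likelihood_arrays(forest, data)
    ev = data.event.astype(float)
    best_lam, best_loss = lambda_grid[0], np.inf
    for lam in lambda_grid:
        fold_losses = []
        for te in folds:
            tr = np.setdiff1d(np.arange(n), te)
            if ev[te].sum() == 0:
                warnings.warn("cross-validation fold without events; held-out loss uses censor terms only")
            Atr, Dtr = A[tr], D[tr]
            evtr = ev[tr]

            def objective(w, Atr=Atr, Dtr=Dtr, evtr=evtr, lam=lam):
                return (
                    _negloglik(Atr, Dtr, evtr, w) + lam * float(w @ w),
                    _negloglik_grad(Atr, Dtr, evtr, w) + 2.0 * lam * w,
                )

            w = _optimize_weights(objective, forest.n_trees)
            fold_losses.append(_negloglik(A[te], D[te], ev[te], w))
        mean_loss = float(np.mean(fold_losses))
        if mean_loss <= best_loss:  # ties favor the larger lambda (ascending grid)
            best_lam, best_loss = lam, mean_loss
    return best_lam


def fit_rwrsf(data: SurvivalData, config: RWRSFConfig | dict | None = None) -> ForestModel:
    """Full pipeline: fit trees, tune lambda by CV, learn the weights."""
    if config is None:
        config = RWRSFConfig()
    elif isinstance(config, dict):
        config = RWRSFConfig(**config)
    forest = fit_forest(
        data,
        n_trees=config.n_trees,
        mtry=config.mtry,
        min_leaf_events=config.min_leaf_events,
        max_depth=config.max_depth,
        n_split_candidates=config.n_split_candidates,
        seed=config.seed,
    )
    if config.lambda_reg is not None:
        lam = float(config.lambda_reg)
    else:
        lam = select_lambda(forest, data, config.lambda_grid, n_folds=config.cv_folds,
                            seed=config.seed, loss=config.loss)
    forest.weights = learn_weights(forest, data, lam, loss=config.loss)
    forest.lambda_reg = lam
    return forest
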