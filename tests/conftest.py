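import numpy as np
import pytest

from rwsurf import SurvivalData


def weibull_ph_data(n, seed, beta=0.8, n_noise=4, shape=1.1, scale=3000.0, horizon=4018.0):
    """Weibull proportional-hazards data: one signal + noise features.

    The first column drives the hazard through ``exp(beta * x0)``; the
    rest are independent noise. Administrative censoring at ``horizon``.
    """
    rng = np.random.default_rng(seed)
    p = 1 + n_noise
    X = rng.normal(size=(n, p))
    eta = beta * X[:, 0]
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / shape)
    time = np.minimum(t_event, horizon)
    event = (t_event <= horizon).astype(int)
    return SurvivalData(time, event, X, [f"x{j}" for j in range(p)])


def random_censored_fixture(rng, n):
    """Small random right-censored dataset for estimator oracles."""
    time = rng.integers(1, 15, n).astype(float)
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[rng.integers(0, n)] = 1
    return time, event


def nelson_aalen_oracle(time, event):
    """Closed form sum(d/Y): independent loop implementation."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    grid, values = [], []
    H = 0.0
    for t in sorted(set(time[event == 1])):
        d = int(((time == t) & (event == 1)).sum())
        Y = int((time >= t).sum())
        H += d / Y
        grid.append(t)
        values.append(H)
    return np.array(grid), np.array(values)


def logrank_oracle(t1, e1, t2, e2):
    """|O - E| / sqrt(V) by direct looping over pooled event times."""
    t1, t2 = np.asarray(t1, float), np.asarray(t2, float)
    e1, e2 = np.asarray(e1), np.asarray(e2)
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    o_minus_e = 0.0
    var = 0.0
    for u in sorted(set(t[e == 1])):
        d = int(((t == u) & (e == 1)).sum())
        d1 = int(((t1 == u) & (e1 == 1)).sum())
        Y = int((t >= u).sum())
        Y1 = int((t1 >= u).sum())
        o_minus_e += d1 - d * Y1 / Y
        if Y > 1:
            var += d * (Y - d) / (Y - 1) * (Y1 / Y) * (1 - Y1 / Y)
    if var <= 0:
        return 0.0
    return abs(o_minus_e) / np.sqrt(var)


def cindex_oracle(risk, time, event):
    """O(n^2) pairwise loop: comparable pairs t_i < t_j with i an event."""
    comparable = concordant = ties = 0
    n = len(risk)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if time[i] < time[j]:
                comparable += 1
                if risk[i] > risk[j]:
                    concordant += 1
                elif risk[i] == risk[j]:
                    ties += 1
    if comparable == 0:
        return float("nan")
    return (concordant + 0.5 * ties) / comparable


@pytest.fixture
def separable_data():
    """One feature perfectly separating early events from late outcomes."""
    rng = np.random.default_rng(7)
    n = 40
    x0 = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(2, 3, n // 2)])
    noise = rng.normal(size=n)
    time = np.concatenate([rng.uniform(1, 10, n // 2), rng.uniform(90, 100, n // 2)])
    event = np.concatenate([np.ones(n // 2, int), np.r_[np.ones(6, int), np.zeros(n // 2 - 6, int)]])
    X = np.column_stack([x0, noise])
    return SurvivalData(time, event, X, ["risk_marker", "noise"])


@pytest.fixture
def small_signal_data():
    return weibull_ph_data(150, seed=11)
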