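"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the partial likelihood is
a double loop, the AUC an exhaustive pair enumeration, and maximization is
derivative-free.
"""

import numpy as np
from scipy.optimize import minimize


def naive_partial_loglik(beta, times, events, X, weights):
    """Weighted Breslow partial log-likelihood by explicit looping."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        eta_i = float(X[i] @ beta)
        denom = 0.0
        for j in range(len(times)):
            if times[j] >= times[i]:
                denom += weights[j] * np.exp(float(X[j] @ beta))
        ll += weights[i] * (eta_i - np.log(denom))
    return ll


def maximize_partial_loglik(times, events, X, weights, x0=None):
    """Derivative-free maximization of the Breslow partial likelihood."""
    p = X.shape[1]
    x0 = np.zeros(p) if x0 is None else x0
    res = minimize(lambda b: -naive_partial_loglik(b, times, events, X,
                                                   weights),
                   x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000,
                            "maxfev": 20000})
    return res.x


def pairwise_auc(times, events, predictions, horizon):
    """Exhaustive Mann-Whitney over case-control pairs (no censoring)."""
    cases = [p for t, e, p in zip(times, events, predictions)
             if t <= horizon and e == 1]
    ctrls = [p for t, e, p in zip(times, events, predictions) if t > horizon]
    num = 0.0
    for pc in cases:
        for pk in ctrls:
            if pc > pk:
                num += 1.0
            elif pc == pk:
                num += 0.5
    return num / (len(cases) * len(ctrls))


def random_survival_frame(rng, n_rows, n_cov=2, tie_prob=0.0):
    """A small random survival dataset as plain arrays."""
    times = rng.exponential(5.0, n_rows)
    if tie_prob > 0:
        times = np.round(times, 0) + 1.0  # force ties
    events = (rng.random(n_rows) < 0.7).astype(int)
    if events.sum() == 0:
        events[int(rng.integers(n_rows))] = 1
    X = rng.normal(0.0, 1.0, (n_rows, n_cov))
    return times, events, X
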