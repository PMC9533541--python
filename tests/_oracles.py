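"""Independent brute-force oracles used to validate the fast implementations.

Everything here enumerates definitions directly (risk sets, patient pairs,
sign flips) with no shared code paths with the package internals.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def naive_cox_loglik(beta, X, time, event) -> float:
    """Breslow log partial likelihood by explicit risk-set enumeration."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


def naive_score(beta, X, time, event) -> np.ndarray:
    """Gradient of the Breslow partial likelihood by enumeration."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ beta
    g = np.zeros(X.shape[1])
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            w = np.exp(eta[risk])
            g += X[i] - (w[:, None] * X[risk]).sum(axis=0) / w.sum()
    return g


def naive_baseline_cumhaz(beta, X, time, event):
    """Breslow cumulative baseline hazard at each distinct event time."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ beta
    uniq = np.unique(np.asarray(time)[np.asarray(event) == 1])
    cum = []
    total = 0.0
    for t in uniq:
        d = sum(1 for i in range(len(time)) if time[i] == t and event[i] == 1)
        risk = [j for j in range(len(time)) if time[j] >= t]
        total += d / np.sum(np.exp(eta[risk]))
        cum.append(total)
    return uniq, np.array(cum)


def naive_concordance(pi, time, event):
    """Pairwise enumeration of the comparable-pair concordance index."""
    pi = np.asarray(pi, float)
    conc = ties = comp = 0
    n = len(time)
    for i, j in product(range(n), range(n)):
        if i == j or time[i] >= time[j]:
            continue
        if event[i] != 1:
            continue  # earlier time must be an observed event
        comp += 1
        if pi[i] > pi[j]:
            conc += 1
        elif pi[i] == pi[j]:
            ties += 1
    if comp == 0:
        return None, 0
    return (conc + 0.5 * ties) / comp, comp


def exact_wilcoxon_greater(d: np.ndarray) -> float:
    """Exact one-sided (greater) signed-rank p-value by enumerating all sign
    assignments; zeros discarded."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 2**n
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs:
            count += 1
    return count / total
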