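"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written from the defining formula with explicit loops or a
generic optimizer, sharing no code with the package's computation path.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def concordance_oracle(risk, time, event, tau=np.inf):
    """Exhaustive all-pairs concordance: comparable iff t_i < t_j, d_i = 1,
    t_i < tau; concordant iff risk_i > risk_j, ties credit 0.5."""
    n = len(risk)
    comparable = 0
    concordant = 0.0
    for i in range(n):
        for j in range(n):
            if event[i] == 1 and time[i] < time[j] and time[i] < tau:
                comparable += 1
                if risk[i] > risk[j]:
                    concordant += 1.0
                elif risk[i] == risk[j]:
                    concordant += 0.5
    return concordant / comparable


def breslow_loglik_naive(beta, X, time, event):
    """Written-out Breslow partial log-likelihood (loops over event times)."""
    beta = np.asarray(beta, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = np.flatnonzero((time == t) & (event == 1))
        risk_set = np.flatnonzero(time >= t)
        ll += (X[deaths] @ beta).sum()
        ll -= len(deaths) * logsumexp(X[risk_set] @ beta)
    return ll


def maximize_breslow_naive(X, time, event):
    """Maximize the written-out partial likelihood with a generic optimizer."""
    k = X.shape[1]
    res = minimize(
        lambda b: -breslow_loglik_naive(b, X, time, event),
        x0=np.zeros(k),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    return res.x


def association_oracle(Z, mask):
    """Double-loop absolute mean cross-product matrix."""
    sub = np.asarray(Z, float)[np.asarray(mask, bool)]
    n, p = sub.shape
    C = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            s = 0.0
            for h in range(n):
                s += sub[h, i] * sub[h, j]
            C[i, j] = abs(s / n)
    return C
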