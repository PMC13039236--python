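"""Independent oracles used only by the test suite.

Each oracle is a second, deliberately simple implementation derived
directly from first principles (the likelihood, a sort, the cross-product
formula), kept apart from the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Newton–Raphson MLE for logistic regression, from the likelihood.

    ℓ(b) = Σ y·Xb − log(1 + exp(Xb)); gradient Xᵀ(y − μ); Hessian
    −XᵀWX with W = diag(μ(1−μ)).  Written independently of the library's
    IRLS implementation (explicit half-stepping on likelihood decrease).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.zeros(X.shape[1])

    def loglik(beta):
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(b)
    for _ in range(max_iter):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        hess = -(X.T * (mu * (1.0 - mu))) @ X
        step = np.linalg.solve(hess, -grad)
        t = 1.0
        while loglik(b + t * step) < ll - 1e-12 and t > 1e-8:
            t /= 2.0
        b = b + t * step
        new_ll = loglik(b)
        if np.max(np.abs(t * step)) < tol:
            break
        ll = new_ll
    return b


def interp_quantile(values, q):
    """Linear-interpolation quantile by explicit sort (numpy-independent)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def upper_tail_flags(values, q=0.75):
    """Brute-force 'strictly above the q-quantile' flags."""
    thr = interp_quantile(values, q)
    return [1 if v > thr else 0 for v in values]


def lower_tail_flags(values, q=0.25):
    """Brute-force 'strictly below the q-quantile' flags."""
    thr = interp_quantile(values, q)
    return [1 if v < thr else 0 for v in values]


def cross_product_or(cases_exp, total_exp, cases_ref, total_ref):
    """Crude odds ratio of an exposed cell against a reference cell."""
    a = cases_exp
    b = total_exp - cases_exp
    c = cases_ref
    d = total_ref - cases_ref
    return (a / b) / (c / d)
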