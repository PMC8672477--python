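"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — loops, enumeration and grid search —
and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_confusion(risks, outcomes, threshold):
    """Confusion counts by an explicit loop (positive iff risk > threshold)."""
    tp = fp = tn = fn = 0
    for r, y in zip(risks, outcomes):
        if r > threshold:
            if y == 1:
                tp += 1
            else:
                fp += 1
        else:
            if y == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def pairwise_auc(risks, outcomes):
    """AUC by enumerating every case-control pair (ties count half)."""
    cases = [r for r, y in zip(risks, outcomes) if y == 1]
    controls = [r for r, y in zip(risks, outcomes) if y == 0]
    total = 0.0
    for c, d in itertools.product(cases, controls):
        if c > d:
            total += 1.0
        elif c == d:
            total += 0.5
    return total / (len(cases) * len(controls))


def _loglik(y, eta):
    # numerically safe log-likelihood of a Bernoulli-logit model
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_logistic(y, covariate=None, offset=None, n_zoom=9, half_width=8.0, n_pts=41):
    """Maximise the logistic log-likelihood by iteratively refined grid search.

    Derivative-free and independent of IRLS.  Each zoom shrinks the search
    half-width to four grid steps around the current argmax, giving a final
    resolution far below 1e-4 on the coefficients.
    """
    y = np.asarray(y, dtype=float)
    off = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if covariate is None:
        center = np.array([0.0])
        w = half_width
        for _ in range(n_zoom):
            grid = np.linspace(center[0] - w, center[0] + w, n_pts)
            lls = [_loglik(y, a + off) for a in grid]
            center = np.array([grid[int(np.argmax(lls))]])
            w *= 4.0 / (n_pts - 1)
        return center
    x = np.asarray(covariate, dtype=float)
    center = np.zeros(2)
    w = half_width
    for _ in range(n_zoom):
        ga = np.linspace(center[0] - w, center[0] + w, n_pts)
        gb = np.linspace(center[1] - w, center[1] + w, n_pts)
        best, best_ll = None, -np.inf
        for a in ga:
            etas = a + np.outer(gb, x) + off
            lls = np.sum(y * etas - np.logaddexp(0.0, etas), axis=1)
            j = int(np.argmax(lls))
            if lls[j] > best_ll:
                best_ll, best = lls[j], (a, gb[j])
        center = np.array(best)
        w *= 4.0 / (n_pts - 1)
    return center


def random_instance(rng, n_min=4, n_max=12):
    """A small random risk/outcome instance with both classes present."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        risks = rng.random(n)
        outcomes = rng.integers(0, 2, n)
        if 0 < outcomes.sum() < n:
            return risks, outcomes
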