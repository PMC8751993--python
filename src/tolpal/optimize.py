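"""Derivative-free compass/pattern search.

A deliberately simple, fully deterministic coordinate pattern search: poll
+/- each coordinate at the current mesh size, move opportunistically to the
first improvement (expanding the mesh x2), contract the mesh x0.5 after an
unsuccessful poll, and stop when the mesh drops below ``tol`` or the
evaluation budget is exhausted.  Callers are expected to transform their
parameters (e.g. to log space) so that box constraints hold by construction
and the mesh is a relative step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatternSearchResult", "pattern_search"]


@dataclass
class PatternSearchResult:
    x: np.ndarray
    fun: float
    n_evals: int
    converged: bool
    improved: bool               # beat the initial point at least once
    trace: list = field(default_factory=list)  # (n_evals, fun) at each accept


def pattern_search(
    f,
    x0,
    step0: float = 0.5,
    tol: float = 1e-6,
    max_evals: int = 500,
    expand: float = 2.0,
    contract: float = 0.5,
    scales=None,
    opportunistic: bool = False,
) -> PatternSearchResult:
    """Minimise ``f`` from ``x0`` by compass search.

    ``scales`` gives per-coordinate step multipliers (default 1).  The search
    is deterministic: polling order is fixed (+e0, -e0, +e1, ...).  By
    default every direction is polled and the best improvement is taken;
    ``opportunistic`` accepts the first improving direction instead.
    """
    x = np.asarray(x0, dtype=float).copy()
    ndim = x.size
    scales = np.ones(ndim) if scales is None else np.asarray(scales, float)
    cache: dict[tuple, float] = {}

    n_evals = 0

    def ev(pt):
        nonlocal n_evals
        key = tuple(np.round(pt, 12))
        if key in cache:
            return cache[key]
        n_evals += 1
        val = float(f(pt))
        if not np.isfinite(val):
            val = np.inf
        cache[key] = val
        return val

    fx = ev(x)
    trace = [(n_evals, fx)]
    mesh = float(step0)
    improved = False
    converged = False

    while n_evals < max_evals:
        if mesh < tol:
            converged = True
            break
        best_ft, best_x = fx, None
        stop = False
        for i in range(ndim):
            for sign in (1.0, -1.0):
                if n_evals >= max_evals:
                    stop = True
                    break
                trial = x.copy()
                trial[i] += sign * mesh * scales[i]
                ft = ev(trial)
                if ft < best_ft:
                    best_ft, best_x = ft, trial
                    if opportunistic:
                        stop = True
                        break
            if stop:
                break
        if best_x is not None:
            x, fx = best_x, best_ft
            improved = True
            trace.append((n_evals, fx))
            mesh = min(mesh * expand, step0 * 2)
        else:
            mesh *= contract

    return PatternSearchResult(x=x, fun=fx, n_evals=n_evals,
                               converged=converged, improved=improved,
                               trace=trace)
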