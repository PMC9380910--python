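"""Proximal-gradient solver for smooth-loss + l1 problems with box constraints.

Used by both the margin-based feature selector (non-negative weights) and the
sign-constrained Lotka-Volterra regression. Backtracking line search on the
smooth part; the l1 term and the box constraints are handled in the proximal
step (soft-threshold followed by clipping, which is the exact prox of
l1 + box-indicator for separable boxes).
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def prox_l1_box(
    v: np.ndarray,
    step_times_l1: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    out = np.sign(v) * np.maximum(np.abs(v) - step_times_l1, 0.0)
    return np.clip(out, lower, upper)


def proximal_gradient(
    f_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    l1_weights: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    step0: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Minimise f(x) + sum(l1_weights * |x|) subject to lower <= x <= upper.

    Returns (solution, converged). The penalised objective is guaranteed not
    to exceed its value at ``x0`` (monotone backtracking).
    """
    x = np.clip(np.asarray(x0, dtype=float).copy(), lower, upper)
    f, g = f_and_grad(x)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite objective at start")
    pen = f + float(np.sum(l1_weights * np.abs(x)))
    step = step0
    converged = False
    for _ in range(max_iter):
        # backtracking until sufficient decrease of the smooth part
        for _bt in range(60):
            x_new = prox_l1_box(x - step * g, step * l1_weights, lower, upper)
            diff = x_new - x
            sq = float(diff @ diff)
            f_new, g_new = f_and_grad(x_new)
            if f_new <= f + float(g @ diff) + 0.5 * sq / step + 1e-12:
                break
            step *= 0.5
        pen_new = f_new + float(np.sum(l1_weights * np.abs(x_new)))
        if pen_new > pen + 1e-12:  # numerical guard: never move uphill
            break
        move = float(np.max(np.abs(x_new - x))) if x_new.size else 0.0
        x, f, g, pen = x_new, f_new, g_new, pen_new
        step = min(step * 1.5, 1e6)
        if move < tol:
            converged = True
            break
        if not np.isfinite(f):
            raise FloatingPointError("non-finite objective during optimisation")
    return x, converged
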