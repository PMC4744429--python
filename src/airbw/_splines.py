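"""Penalized B-spline (P-spline) basis and difference-penalty construction."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["pspline_basis", "bspline_design", "difference_penalty"]


def _knot_vector(x: np.ndarray, n_interior: int, degree: int, rule: str) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if rule == "quantile":
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, probs)
    elif rule == "equidistant":
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    else:
        raise ValueError(f"unknown knot rule {rule!r}")
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """Dense B-spline design matrix; x clipped to the knot span."""
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def difference_penalty(p: int, order: int) -> np.ndarray:
    """K = D_r' D_r for r-th order differences of p coefficients.

    Positive semidefinite with null space of dimension ``order`` (degree-
    (order-1) polynomials in the coefficients are unpenalized).
    """
    D = np.eye(p)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D.T @ D


def pspline_basis(x, n_knots: int = 20, degree: int = 3, penalty_order: int = 2,
                  knot_rule: str = "equidistant"):
    """B-spline basis with a random-walk difference penalty.

    Returns ``(B, K, knots)``: the n x p design matrix (rows sum to one by
    the partition of unity), the p x p penalty, and the full knot vector.
    Requires at least ``n_knots + degree + 1`` distinct x values so the basis
    is identified by the data.
    """
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < n_knots + degree + 1:
        raise ValueError(
            f"need at least {n_knots + degree + 1} distinct values for "
            f"{n_knots} interior knots of degree {degree}")
    knots = _knot_vector(x, n_knots, degree, knot_rule)
    B = bspline_design(x, knots, degree)
    K = difference_penalty(B.shape[1], penalty_order)
    return B, K, knots


def bspline_derivative_design(xgrid: np.ndarray, knots: np.ndarray, degree: int,
                              p: int) -> np.ndarray:
    """Matrix G with G @ theta = d/dx of the spline at xgrid (analytic)."""
    lo, hi = knots[degree], knots[-degree - 1]
    xg = np.clip(np.asarray(xgrid, dtype=float), lo, hi)
    G = np.empty((xg.size, p))
    for j in range(p):
        coef = np.zeros(p)
        coef[j] = 1.0
        G[:, j] = BSpline(knots, coef, degree).derivative()(xg)
    return G
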