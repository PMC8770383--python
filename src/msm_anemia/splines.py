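"""Restricted (natural) cubic spline basis in Harrell's parameterization.

For k ordered knots t_1 < ... < t_k the basis is the linear term plus k-2
nonlinear terms; nonlinear term j is a normalized combination of truncated
cubes that vanishes for x <= t_1 and is linear beyond t_k:

    f_j(x) = [ (x - t_j)+^3
               - (x - t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
               + (x - t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2
"""

from __future__ import annotations

import numpy as np


def rcs_knots(x, n_knots: int = 5) -> np.ndarray:
    """Knot placement at Harrell's default quantiles for five knots."""
    x = np.asarray(x, dtype=float)
    if n_knots == 5:
        q = (0.05, 0.275, 0.50, 0.725, 0.95)
    elif n_knots == 4:
        q = (0.05, 0.35, 0.65, 0.95)
    elif n_knots == 3:
        q = (0.10, 0.50, 0.90)
    else:
        q = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(x, q)
    if len(np.unique(knots)) < len(knots):
        # fall back to evenly spaced knots over the observed range
        knots = np.linspace(x.min(), x.max(), n_knots)
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Columns: (x, s_1, ..., s_{k-2}); requires >= 3 strictly increasing knots."""
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise ValueError("rcs_basis requires at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = len(knots)
    norm = (knots[-1] - knots[0]) ** 2

    def tp3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            tp3(x - knots[j])
            - tp3(x - knots[k - 2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[k - 2])
            + tp3(x - knots[-1]) * (knots[k - 2] - knots[j]) / (knots[-1] - knots[k - 2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)
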