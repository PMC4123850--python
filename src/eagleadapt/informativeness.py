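"""Blackwell comparison of information structures.

An information structure is a column-stochastic matrix ``P(X | signal)``.
Signal ``W`` is at least as informative as signal ``Z`` when ``Z``'s
conditional distributions are a stochastic garbling of ``W``'s, i.e. when a
column-stochastic matrix ``T`` exists with ``P_Z = P_W @ T``.  Existence is
decided constructively by a linear program minimizing the worst-case
residual subject to the stochasticity constraints, which returns either a
witness ``T`` or a certificate that no garbling fits within tolerance.

For the eagle site model this formalizes why the fledging-success signal
beats the action as a source of information about next-year occupancy: the
action-conditional occupancy matrix is the outcome-conditional one
post-multiplied by the explicit garbling of :func:`action_garbling`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from .model_core import SuccessProbs

__all__ = ["at_least_as_informative", "action_garbling"]


def action_garbling(probs: SuccessProbs) -> np.ndarray:
    """Garbling from outcome-conditioning to action-conditioning.

    Columns correspond to the site's (state, action) — empty/unrestricted,
    occupied/unrestricted, occupied/restricted — and rows to this year's
    outcome categories (empty, occupied-unsuccessful, occupied-successful).
    Post-multiplying the outcome-conditional occupancy matrix by this
    matrix reproduces the plain state-transition matrix.
    """
    pu, pr = probs.p_u, probs.p_r
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0 - pu, 1.0 - pr],
            [0.0, pu, pr],
        ]
    )


def at_least_as_informative(
    P_W: np.ndarray, P_Z: np.ndarray, tol: float = 1e-8
) -> tuple[bool, np.ndarray | None]:
    """Decide whether signal ``W`` Blackwell-dominates signal ``Z``.

    Both arguments are conditional probability arrays over a common
    outcome space ``X`` (rows), one column per signal value.  Returns
    ``(True, T)`` with a witness garbling when a column-stochastic ``T``
    achieves ``max |P_Z - P_W @ T| <= tol``, else ``(False, None)``.
    """
    P_W = np.asarray(P_W, dtype=float)
    P_Z = np.asarray(P_Z, dtype=float)
    if P_W.ndim != 2 or P_Z.ndim != 2 or P_W.shape[0] != P_Z.shape[0]:
        raise ValueError(
            f"structures must share the outcome space: {P_W.shape} vs {P_Z.shape}"
        )
    n_x, n_w = P_W.shape
    n_z = P_Z.shape[1]
    # variables: vec(T) column-major (n_w * n_z), then the residual bound t
    n_var = n_w * n_z + 1
    c = np.zeros(n_var)
    c[-1] = 1.0
    # |(P_W T - P_Z)[x, z]| <= t for every cell
    rows = []
    rhs = []
    for z in range(n_z):
        block = np.zeros((n_x, n_var))
        block[:, z * n_w : (z + 1) * n_w] = P_W
        block[:, -1] = -1.0
        rows.append(block)
        rhs.append(P_Z[:, z])
        rows.append(-block.copy())
        rows[-1][:, -1] = -1.0
        rhs.append(-P_Z[:, z])
    A_ub = np.vstack(rows)
    b_ub = np.concatenate(rhs)
    # column sums of T equal 1
    A_eq = np.zeros((n_z, n_var))
    for z in range(n_z):
        A_eq[z, z * n_w : (z + 1) * n_w] = 1.0
    b_eq = np.ones(n_z)
    bounds = [(0.0, 1.0)] * (n_w * n_z) + [(0.0, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        return False, None
    if res.x[-1] > tol:
        return False, None
    T = res.x[:-1].reshape(n_z, n_w).T
    return True, T
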