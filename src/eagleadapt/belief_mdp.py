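"""Belief-state dynamic programming for structural uncertainty.

The unknown disturbance model is carried as a belief vector ``B`` over the
three candidate models, updated each year by Bayes rule from the observed
signal and next-year occupancy.  The management problem then becomes an
ordinary discounted MDP on the augmented state ``(S, B)``: occupancy count
``S`` in ``0..N`` and ``B`` discretized on a regular simplex grid.  Values
at off-grid posterior beliefs are barycentric interpolations within the
containing simplex cell, which makes the discretized problem itself a
proper finite MDP.

Three solvers are provided:

* :func:`solve_certain` — no structural uncertainty, a plain MDP over
  occupancy for one model at a given hare level;
* :func:`solve_active` — the full belief-MDP optimum, which anticipates
  future belief changes and therefore may "probe";
* :func:`solve_passive` — for each grid belief, the rule of the MDP whose
  transition is the belief-averaged no-signal kernel with the belief held
  fixed (the classical passive adaptive-management strategy).

The fixed point of :func:`solve_active` is computed by Bellman-improvement
sweeps interleaved with fixed-policy evaluation sweeps (modified policy
iteration); iteration stops when a full improvement sweep changes the value
surface by less than ``tol`` in sup norm.  Starting from the zero surface
(all rewards are non-negative) the sequence increases monotonically to the
optimum.  Ties in the action argmax break toward the smallest number of
restrictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .model_core import (
    SiteParams,
    SuccessProbs,
    UncertaintyCase,
    success_probabilities,
)
from .multisite import JointKernel, build_kernel, build_case_kernels, garble

__all__ = [
    "BeliefGrid",
    "RewardSpec",
    "BeliefPolicy",
    "CertainPolicy",
    "belief_update",
    "expected_reward",
    "solve_certain",
    "solve_active",
    "solve_passive",
    "solve_case",
    "value_gain",
    "policy_frame",
]

log = logging.getLogger(__name__)


class BeliefGrid:
    """Regular grid on the 3-model probability simplex.

    Points have coordinates ``k / order``; ``order=100`` gives steps of
    0.01.  The three vertices (complete certainty in one model) are always
    grid points.
    """

    def __init__(self, order: int = 100):
        if order < 1:
            raise ValueError("grid order must be >= 1")
        self.order = int(order)
        m = self.order
        lut = np.full((m + 2, m + 2), -1, dtype=np.int64)
        pts = []
        for i in range(m + 1):
            for j in range(m - i + 1):
                lut[i, j] = len(pts)
                pts.append((i / m, j / m, (m - i - j) / m))
        self.points = np.array(pts)  #: (G, 3) belief vectors
        self._lut = lut
        if len(pts) >= np.iinfo(np.int16).max:
            raise ValueError("grid order too large for int16 indexing")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def vertex_index(self, model: int) -> int:
        m = self.order
        return int((self._lut[m, 0], self._lut[0, m], self._lut[0, 0])[model])

    def snap(self, B: np.ndarray) -> np.ndarray:
        """Nearest grid-point index for each belief (largest-remainder)."""
        B = np.atleast_2d(np.asarray(B, dtype=float))
        m = self.order
        x = B * m
        fl = np.floor(x).astype(np.int64)
        rem = x - fl
        deficit = m - fl.sum(axis=1)
        # add 1 to the `deficit` coordinates with the largest remainders
        rank = np.argsort(np.argsort(-rem, axis=1, kind="stable"), axis=1)
        fl += rank < deficit[:, None]
        return self._lut[fl[:, 0], fl[:, 1]]

    def barycentric(self, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vertex indices and weights of the cell containing each belief.

        Returns ``(idx, w)`` with shapes ``(..., 3)``; the interpolated
        value of a surface ``V`` at ``B`` is ``sum_k w_k V[idx_k]``.
        """
        B = np.asarray(B, dtype=float)
        B = np.clip(B, 0.0, None)
        B = B / B.sum(axis=-1, keepdims=True)
        m = self.order
        x1, x2 = B[..., 0] * m, B[..., 1] * m
        i = np.minimum(np.floor(x1).astype(np.int64), m)
        j = np.minimum(np.floor(x2).astype(np.int64), m)
        f1, f2 = x1 - i, x2 - j
        lower = f1 + f2 <= 1.0
        lut = self._lut
        idx_a, idx_b = lut[i + 1, j], lut[i, j + 1]
        idx = np.stack(
            [
                np.where(lower, lut[i, j], lut[i + 1, j + 1]),
                np.where(lower, idx_a, idx_b),
                np.where(lower, idx_b, idx_a),
            ],
            axis=-1,
        )
        w = np.stack(
            [
                np.where(lower, 1.0 - f1 - f2, f1 + f2 - 1.0),
                np.where(lower, f1, 1.0 - f1),
                np.where(lower, f2, 1.0 - f2),
            ],
            axis=-1,
        )
        w = np.clip(w, 0.0, None)
        w = w / w.sum(axis=-1, keepdims=True)
        idx = np.where(idx < 0, 0, idx)  # unreachable vertices carry ~0 weight
        return idx, w


@dataclass(frozen=True)
class RewardSpec:
    """Per-year utility trading breeding success against hiker access.

    The default Cobb-Douglas form is ``E[Y]**alpha * (N - A)**(1 - alpha)``
    with ``E[Y]`` the expected number of successful fledgings given
    (S, A, B); the ``linear`` form is ``alpha * E[Y] + (1-alpha) * (N-A)``.
    """

    alpha: float = 0.85
    form: str = "cobb_douglas"

    def __post_init__(self) -> None:
        if self.form not in ("cobb_douglas", "linear"):
            raise ValueError(f"unknown reward form {self.form!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def expected_reward(
    S: int,
    A: int,
    B: np.ndarray,
    probs: list[SuccessProbs],
    reward: RewardSpec,
    params: SiteParams,
) -> float:
    """Utility of action ``A`` in state ``S`` under belief ``B``."""
    if A > S:
        raise ValueError("cannot restrict more sites than are occupied")
    B = np.asarray(B, dtype=float)
    ey_models = np.array([A * p.p_r + (S - A) * p.p_u for p in probs])
    ey = float(B @ ey_models)
    access = params.n_sites - A
    if reward.form == "cobb_douglas":
        return float(ey**reward.alpha * access ** (1.0 - reward.alpha))
    return float(reward.alpha * ey + (1.0 - reward.alpha) * access)


def _reward_grid(
    S: int,
    A: int,
    W: np.ndarray,
    probs: list[SuccessProbs],
    reward: RewardSpec,
    params: SiteParams,
) -> np.ndarray:
    ey_models = np.array([A * p.p_r + (S - A) * p.p_u for p in probs])
    ey = W @ ey_models
    access = params.n_sites - A
    if reward.form == "cobb_douglas":
        return ey**reward.alpha * access ** (1.0 - reward.alpha)
    return reward.alpha * ey + (1.0 - reward.alpha) * access


def belief_update(
    B: np.ndarray,
    kernels: list[JointKernel],
    S: int,
    A: int,
    Y: tuple[int, ...] | int,
    S_next: int,
) -> np.ndarray:
    """Bayes posterior over models after observing (Y, S_next) from (S, A).

    ``Y`` is a (Y1, Y2) pair in mode ``full``, a single count in the scalar
    modes, and ignored (pass ``()``) in mode ``none``.
    """
    B = np.asarray(B, dtype=float)
    if isinstance(Y, (int, np.integer)):
        Y = (int(Y),)
    obs = tuple(int(y) for y in Y) + (int(S_next),)
    tables = [k.table(S, A) for k in kernels]
    # signal values outside the feasible range have zero probability
    in_range = all(0 <= o < n for o, n in zip(obs, tables[0].shape))
    like = (
        np.array([t[obs] for t in tables])
        if in_range
        else np.zeros(len(tables))
    )
    post = B * like
    total = post.sum()
    if total <= 0.0:
        raise ValueError(
            f"observation (Y={Y}, S_next={S_next}) from (S={S}, A={A}) is "
            "impossible under every candidate model"
        )
    return post / total


# ---------------------------------------------------------------------------
# certain-model MDP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CertainPolicy:
    """Optimal rule of the no-uncertainty MDP for one model."""

    hare: float
    actions: np.ndarray  #: (N+1,) restricted sites per occupancy count
    values: np.ndarray  #: (N+1,) discounted values
    iterations: int
    residual: float


def solve_certain(
    case: UncertaintyCase,
    model_index: int,
    params: SiteParams,
    reward: RewardSpec | None = None,
    hare: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> CertainPolicy:
    """Value-iteration solution with the true model known.

    The hare index enters as a covariate of the success probabilities;
    ``hare=None`` uses ``params.hare``.
    """
    reward = reward or RewardSpec(alpha=params.alpha)
    hare = params.hare if hare is None else float(hare)
    p = case.models[model_index].params(params).with_(hare=hare)
    probs = success_probabilities(p)
    kern = build_kernel(p, probs, mode="none")
    N = params.n_sites
    pairs = kern.pairs()
    P = np.array([kern.table(S, A) for S, A in pairs])  # (n_pairs, N+1)
    R = np.array(
        [expected_reward(S, A, [1.0], [probs], reward, params) for S, A in pairs]
    )
    starts = np.array([i for i, (S, A) in enumerate(pairs) if A == 0])
    V = np.zeros(N + 1)
    delta = np.inf
    for it in range(1, max_iter + 1):
        Q = R + params.discount * (P @ V)
        V_new = np.maximum.reduceat(Q, starts)
        delta = float(np.max(np.abs(V_new - V)))
        V = V_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"certain-model value iteration did not converge "
                           f"(residual {delta:.3g} after {max_iter} sweeps)")
    Q = R + params.discount * (P @ V)
    actions = np.array(
        [int(np.argmax(Q[s : s + S + 1])) for S, s in zip(range(N + 1), starts)]
    )
    return CertainPolicy(hare=hare, actions=actions, values=V,
                         iterations=it, residual=delta)


# ---------------------------------------------------------------------------
# belief-MDP preparation
# ---------------------------------------------------------------------------


@njit(cache=False)
def _q_kernel(PV, idx, wgt, W, g_sel, out):
    """Expected interpolated continuation value for selected grid points.

    ``PV[o, i, g]`` is ``sum_s P_i(o, s) V[s, g]`` for outcome group ``o``
    and model ``i``; ``idx/wgt`` are the barycentric vertices and weights
    of the posterior belief of group ``o`` seen from grid point ``g``.
    """
    n_g = PV.shape[0]
    for t in range(g_sel.size):
        g = g_sel[t]
        w0, w1, w2 = W[g, 0], W[g, 1], W[g, 2]
        acc = 0.0
        for o in range(n_g):
            s = 0.0
            for k in range(3):
                jj = idx[g, o, k]
                s += wgt[g, o, k] * (
                    w0 * PV[o, 0, jj] + w1 * PV[o, 1, jj] + w2 * PV[o, 2, jj]
                )
            acc += s
        out[t] = acc


class _Prepped:
    """Per-(S, A) solver tables for one uncertainty case and signal mode.

    Outcomes ``(signal, S_next)`` whose model-likelihood vectors are
    proportional lead to the same posterior from every prior, so they are
    grouped (their probabilities summed per ``S_next``) before posterior
    interpolation.  For the full signal this collapses the outcome space to
    the distinct (Y1, Y2) pairs, because the shared colonization and
    re-occupancy parameters make ``S_next`` uninformative given the
    success counts.
    """

    def __init__(self, kernels, probs, grid, reward, params):
        if len({k.mode for k in kernels}) != 1:
            raise ValueError("kernels must share one signal mode")
        self.mode = kernels[0].mode
        self.grid = grid
        self.params = params
        self.N = kernels[0].n_sites
        W = grid.points
        self.pairs: list[tuple[int, int]] = kernels[0].pairs()
        self.pair_index = {p: i for i, p in enumerate(self.pairs)}
        self.R: list[np.ndarray] = []
        self.P: list[np.ndarray] = []
        self.idx: list[np.ndarray] = []
        self.wgt: list[np.ndarray] = []
        n1 = self.N + 1
        for (S, A) in self.pairs:
            L = np.stack([k.flat(S, A) for k in kernels], axis=-1)  # (sig, S+, 3)
            L = L.reshape(-1, 3)
            tot = L.sum(axis=1)
            keep = np.nonzero(tot > 0.0)[0]
            s_next = (keep % n1).astype(np.int64)
            dirs = L[keep] / tot[keep, None]
            _, inv = np.unique(np.round(dirs, 12), axis=0, return_inverse=True)
            n_g = int(inv.max()) + 1
            P = np.zeros((n_g, n1, 3))
            np.add.at(P, (inv, s_next), L[keep])
            P = np.ascontiguousarray(P.transpose(0, 2, 1))  # (n_g, 3, N+1)
            d = P.sum(axis=2)  # (n_g, 3) total likelihood per model
            d = d / d.sum(axis=1, keepdims=True)
            post = W[:, None, :] * d[None, :, :]
            post = post / np.maximum(post.sum(axis=2, keepdims=True), 1e-300)
            gidx, gw = grid.barycentric(post)
            self.P.append(P)
            self.idx.append(gidx.astype(np.int16))
            self.wgt.append(gw.astype(np.float32))
            self.R.append(_reward_grid(S, A, W, probs, reward, params))

    def q_values(self, pair: int, V: np.ndarray, g_sel: np.ndarray) -> np.ndarray:
        """R + delta * E[V(S+, B+)] for one (S, A) at selected grid points."""
        P = self.P[pair]
        n_g = P.shape[0]
        PV = (P.reshape(n_g * 3, -1) @ V).reshape(n_g, 3, -1)
        out = np.empty(g_sel.size)
        _q_kernel(PV, self.idx[pair], self.wgt[pair],
                  self.grid.points, g_sel, out)
        return self.R[pair][g_sel] + self.params.discount * out


# ---------------------------------------------------------------------------
# policies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeliefPolicy:
    """Decision rule and value surface on occupancy x belief grid."""

    grid: BeliefGrid
    mode: str
    strategy: str  #: "active" or "passive"
    actions: np.ndarray  #: (N+1, G) int
    values: np.ndarray  #: (N+1, G) float
    iterations: int
    residual: float

    def action(self, S: int, B: np.ndarray) -> int:
        """Action at occupancy ``S`` and the grid point nearest to ``B``."""
        g = int(self.grid.snap(np.asarray(B))[0])
        return int(self.actions[S, g])


def policy_frame(policy: BeliefPolicy) -> pd.DataFrame:
    """Long format (S, b1, b2, b3, action, value), ternary-plot ready."""
    W = policy.grid.points
    n_states, G = policy.values.shape
    recs = {
        "S": np.repeat(np.arange(n_states), G),
        "b1": np.tile(W[:, 0], n_states),
        "b2": np.tile(W[:, 1], n_states),
        "b3": np.tile(W[:, 2], n_states),
        "action": policy.actions.ravel(),
        "value": policy.values.ravel(),
    }
    return pd.DataFrame(recs)


def _improvement_sweep(prep: _Prepped, V: np.ndarray):
    """One Bellman max sweep; returns (V_new, policy)."""
    G = prep.grid.n_points
    N = prep.N
    all_g = np.arange(G)
    V_new = np.empty_like(V)
    pol = np.zeros((N + 1, G), dtype=np.int16)
    for S in range(N + 1):
        q = np.empty((S + 1, G))
        for A in range(S + 1):
            q[A] = prep.q_values(prep.pair_index[(S, A)], V, all_g)
        pol[S] = np.argmax(q, axis=0)  # first max -> smallest A on ties
        V_new[S] = q[pol[S], all_g]
    return V_new, pol


def _evaluation_sweep(prep: _Prepped, V: np.ndarray, pol: np.ndarray) -> np.ndarray:
    """One fixed-policy expectation sweep."""
    V_new = np.empty_like(V)
    for S in range(prep.N + 1):
        for A in np.unique(pol[S]):
            g_sel = np.nonzero(pol[S] == A)[0]
            V_new[S, g_sel] = prep.q_values(prep.pair_index[(S, int(A))], V, g_sel)
    return V_new


def solve_active(
    kernels: list[JointKernel],
    probs: list[SuccessProbs],
    grid: BeliefGrid,
    params: SiteParams,
    reward: RewardSpec | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 5000,
    inner_sweeps: int = 60,
) -> BeliefPolicy:
    """Optimal active-learning policy on the belief grid.

    ``kernels`` are the per-model joint kernels in a common signal mode;
    ``probs`` the matching per-model success probabilities (for rewards).
    Stops when a Bellman improvement sweep moves the value surface by less
    than ``tol`` in sup norm; raises if ``max_sweeps`` total sweeps are
    exhausted first.
    """
    reward = reward or RewardSpec(alpha=params.alpha)
    prep = _Prepped(kernels, probs, grid, reward, params)
    V = np.zeros((prep.N + 1, grid.n_points))
    sweeps = 0
    while True:
        V_new, pol = _improvement_sweep(prep, V)
        sweeps += 1
        delta = float(np.max(np.abs(V_new - V)))
        V = V_new
        log.info("active solve: sweep %d residual %.3g", sweeps, delta)
        if delta < tol:
            break
        if sweeps >= max_sweeps:
            raise RuntimeError(
                f"belief-MDP iteration did not converge: residual {delta:.3g} "
                f"after {sweeps} sweeps"
            )
        for _ in range(inner_sweeps):
            V_new = _evaluation_sweep(prep, V, pol)
            sweeps += 1
            d_in = float(np.max(np.abs(V_new - V)))
            V = V_new
            if d_in < 0.1 * tol or sweeps >= max_sweeps:
                break
    return BeliefPolicy(
        grid=grid, mode=prep.mode, strategy="active",
        actions=pol, values=V, iterations=sweeps, residual=delta,
    )


def solve_passive(
    kernels: list[JointKernel],
    probs: list[SuccessProbs],
    grid: BeliefGrid,
    params: SiteParams,
    reward: RewardSpec | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 20000,
) -> BeliefPolicy:
    """Passive-learning rule: optimize as if beliefs never change.

    For every grid belief ``B`` the occupancy MDP with the B-averaged
    no-signal transition is solved with ``B`` frozen, and its rule
    recorded.  Beliefs would still be updated when the rule is applied;
    the strategy simply does not anticipate that.
    """
    reward = reward or RewardSpec(alpha=params.alpha)
    nosig = [k if k.mode == "none" else garble(k, "none") for k in kernels]
    N = kernels[0].n_sites
    W = grid.points
    G = grid.n_points
    pairs = nosig[0].pairs()
    starts = np.array([i for i, (S, A) in enumerate(pairs) if A == 0])
    # belief-averaged transition and reward per (S, A) x grid point
    PB = np.array(
        [W @ np.stack([k.table(S, A) for k in nosig]) for S, A in pairs]
    )  # (n_pairs, G, N+1)
    R = np.array([_reward_grid(S, A, W, probs, reward, params) for S, A in pairs])
    V = np.zeros((N + 1, G))
    delta = np.inf
    for it in range(1, max_sweeps + 1):
        Q = R + params.discount * np.einsum("pgs,sg->pg", PB, V)
        V_new = np.maximum.reduceat(Q, starts, axis=0)
        delta = float(np.max(np.abs(V_new - V)))
        V = V_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"passive solve did not converge: residual {delta:.3g}"
        )
    Q = R + params.discount * np.einsum("pgs,sg->pg", PB, V)
    pol = np.empty((N + 1, G), dtype=np.int16)
    for S, s in enumerate(starts):
        pol[S] = np.argmax(Q[s : s + S + 1], axis=0)
    log.info("passive solve: %d sweeps, residual %.3g", it, delta)
    return BeliefPolicy(
        grid=grid, mode="none", strategy="passive",
        actions=pol, values=V, iterations=it, residual=delta,
    )


def value_gain(V_signal: np.ndarray, V_nosignal: np.ndarray) -> np.ndarray:
    """Pointwise percent increase in value from using the signal."""
    V_signal = np.asarray(V_signal, dtype=float)
    V_nosignal = np.asarray(V_nosignal, dtype=float)
    if V_signal.shape != V_nosignal.shape:
        raise ValueError("value surfaces must share a grid")
    return 100.0 * (V_signal - V_nosignal) / V_nosignal


def solve_case(
    case: UncertaintyCase,
    params: SiteParams,
    mode: str | None = None,
    grid: BeliefGrid | int = 50,
    strategy: str = "active",
    reward: RewardSpec | None = None,
    tol: float = 1e-6,
    **kwargs,
) -> BeliefPolicy:
    """Convenience wrapper: build kernels for a preset case and solve."""
    if isinstance(grid, int):
        grid = BeliefGrid(grid)
    kernels = build_case_kernels(params, case, mode=mode)
    probs = case.success_probs(params)
    if strategy == "active":
        return solve_active(kernels, probs, grid, params, reward, tol, **kwargs)
    if strategy == "passive":
        return solve_passive(kernels, probs, grid, params, reward, tol, **kwargs)
    raise ValueError(f"unknown strategy {strategy!r}")
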