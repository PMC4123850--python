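"""Exact multi-site kernels by category counting.

With ``N`` exchangeable territories the management state is the number of
occupied sites ``S`` and the action is the number of restricted sites
``A <= S``.  The signals are counts: ``Y1`` successful fledgings at
unrestricted sites and ``Y2`` at restricted sites.  Because sites are
exchangeable and independent given (S, A), the joint distribution of
(Y1, Y2, S_next) is obtained by drawing the ``N - S`` empty, ``S - A``
occupied/unrestricted and ``A`` occupied/restricted sites from their
respective single-site event-table columns and convolving the per-group
multinomial counts; assignments of sites to outcome categories that share
the same (signal, S_next) value are summed.

A :class:`JointKernel` holds one such table per feasible (S, A) pair under
one candidate disturbance model and one signal mode.  The canonical mode is
``"full"`` (both counts tracked); every coarser signal — unrestricted-only,
restricted-only, the total number of successes, or no signal at all — is a
garbling of it (:func:`garble`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .model_core import SiteParams, SuccessProbs, site_event_table

__all__ = [
    "SIGNAL_MODES",
    "JointKernel",
    "build_kernel",
    "build_case_kernels",
    "garble",
    "enumerate_assignments",
    "assignment_table",
    "kernel_frame",
]

#: Recognised signal modes, from finest to coarsest.
SIGNAL_MODES = ("full", "unrestricted_only", "restricted_only", "total", "none")

#: Which target modes each mode can be coarsened to.
_COARSENINGS = {
    "full": {"full", "unrestricted_only", "restricted_only", "total", "none"},
    "unrestricted_only": {"unrestricted_only", "none"},
    "restricted_only": {"restricted_only", "none"},
    "total": {"total", "none"},
    "none": {"none"},
}


@dataclass(frozen=True)
class JointKernel:
    """P(signal, S_next | S, A) for all feasible (S, A) under one model.

    ``tables[(S, A)]`` is an array whose trailing axis is ``S_next`` in
    ``0..n_sites`` and whose leading axes depend on the signal mode:
    ``(Y1, Y2)`` for ``full``, a single signal axis for the three scalar
    modes, and no signal axis for ``none``.  Infeasible pairs (A > S) are
    simply absent.
    """

    n_sites: int
    mode: str
    tables: dict[tuple[int, int], np.ndarray]
    model_index: int | None = None

    def table(self, S: int, A: int) -> np.ndarray:
        if not (0 <= A <= S <= self.n_sites):
            raise ValueError(
                f"infeasible state/action (S={S}, A={A}): the number of "
                "restricted sites can never exceed the number occupied"
            )
        return self.tables[(S, A)]

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.tables)

    def flat(self, S: int, A: int) -> np.ndarray:
        """Table reshaped to (n_signal_values, n_sites + 1)."""
        t = self.table(S, A)
        return t.reshape(-1, self.n_sites + 1)

    def signal_values(self, S: int, A: int) -> list[tuple[int, ...]]:
        """Signal tuples in the row order of :meth:`flat`."""
        t = self.table(S, A)
        if self.mode == "none":
            return [()]
        sig_shape = t.shape[:-1]
        return [idx for idx in np.ndindex(*sig_shape)]


def _group_joint(n: int, p_succ: float, p_n: float, p_s: float) -> np.ndarray:
    """Joint pmf of (successes y, re-occupied o) among n occupied sites.

    Sites succeed independently with ``p_succ``; successful sites are
    re-occupied with ``p_s`` and unsuccessful ones with ``p_n``, so given
    ``y`` the re-occupied count is a sum of two independent binomials.
    """
    out = np.zeros((n + 1, n + 1))
    y = np.arange(n + 1)
    py = binom.pmf(y, n, p_succ)
    for yi in y:
        occ_s = binom.pmf(np.arange(yi + 1), yi, p_s)
        occ_n = binom.pmf(np.arange(n - yi + 1), n - yi, p_n)
        out[yi, : n + 1] = py[yi] * np.convolve(occ_s, occ_n)
    return out


def build_kernel(
    params: SiteParams,
    probs: SuccessProbs,
    mode: str = "full",
    model_index: int | None = None,
) -> JointKernel:
    """Exact joint kernel for ``params.n_sites`` sites under one model.

    The full (Y1, Y2) kernel is assembled group-wise and then coarsened to
    ``mode`` if a coarser signal was requested.
    """
    if mode not in SIGNAL_MODES:
        raise ValueError(f"unknown signal mode {mode!r}; choose from {SIGNAL_MODES}")
    N = params.n_sites
    pc, pn, ps = params.p_c, params.p_n, params.p_s
    tables: dict[tuple[int, int], np.ndarray] = {}
    # per-group distributions depend only on group size; cache by size
    ju_cache = {n: _group_joint(n, probs.p_u, pn, ps) for n in range(N + 1)}
    jr_cache = {n: _group_joint(n, probs.p_r, pn, ps) for n in range(N + 1)}
    e_cache = {n: binom.pmf(np.arange(n + 1), n, pc) for n in range(N + 1)}
    for S in range(N + 1):
        for A in range(S + 1):
            nu, nr, ne = S - A, A, N - S
            ju, jr, e = ju_cache[nu], jr_cache[nr], e_cache[ne]
            # convolve restricted-group occupancy with empty-group occupancy
            re = np.array([np.convolve(jr[y2], e) for y2 in range(nr + 1)])
            out = np.zeros((nu + 1, nr + 1, N + 1))
            for y1 in range(nu + 1):
                for y2 in range(nr + 1):
                    conv = np.convolve(ju[y1], re[y2])
                    out[y1, y2, : conv.size] = conv
            tables[(S, A)] = out
    kernel = JointKernel(n_sites=N, mode="full", tables=tables, model_index=model_index)
    return kernel if mode == "full" else garble(kernel, mode)


def build_case_kernels(params, case, mode: str | None = None) -> list[JointKernel]:
    """Kernels for each candidate model of an uncertainty case.

    ``mode=None`` uses the case's own best signal.
    """
    mode = case.signal_mode if mode is None else mode
    return [
        build_kernel(params, m.success_probs(params), mode=mode, model_index=i)
        for i, m in enumerate(case.models)
    ]


def garble(kernel: JointKernel, target_mode: str) -> JointKernel:
    """Coarsen a kernel's signal; refinement requests are rejected.

    ``"none"`` yields the pure occupancy-transition kernel (marginal over
    all signals).
    """
    if target_mode not in SIGNAL_MODES:
        raise ValueError(f"unknown signal mode {target_mode!r}")
    if target_mode not in _COARSENINGS[kernel.mode]:
        raise ValueError(
            f"cannot refine signal mode {kernel.mode!r} to {target_mode!r}"
        )
    if target_mode == kernel.mode:
        return JointKernel(
            kernel.n_sites,
            kernel.mode,
            {k: v.copy() for k, v in kernel.tables.items()},
            kernel.model_index,
        )
    tables: dict[tuple[int, int], np.ndarray] = {}
    for (S, A), t in kernel.tables.items():
        if kernel.mode == "full":
            if target_mode == "unrestricted_only":
                new = t.sum(axis=1)
            elif target_mode == "restricted_only":
                new = t.sum(axis=0)
            elif target_mode == "none":
                new = t.sum(axis=(0, 1))
            else:  # total successes Y1 + Y2
                nu, nr = t.shape[0] - 1, t.shape[1] - 1
                new = np.zeros((nu + nr + 1, t.shape[2]))
                for y1 in range(nu + 1):
                    for y2 in range(nr + 1):
                        new[y1 + y2] += t[y1, y2]
        else:  # scalar-signal mode -> none
            new = t.sum(axis=0)
        tables[(S, A)] = new
    return JointKernel(kernel.n_sites, target_mode, tables, kernel.model_index)


def enumerate_assignments(n_sites: int, n_categories: int) -> np.ndarray:
    """All compositions of ``n_sites`` into ``n_categories`` ordered parts.

    Rows are counts per category in lexicographic order; there are
    C(n_sites + n_categories - 1, n_categories - 1) of them.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")

    def _comps(n: int, k: int):
        if k == 1:
            yield (n,)
            return
        for first in range(n + 1):
            for rest in _comps(n - first, k - 1):
                yield (first, *rest)

    return np.array(list(_comps(n_sites, n_categories)), dtype=int).reshape(
        -1, n_categories
    )


def assignment_table(
    params: SiteParams, probs: SuccessProbs, S: int, A: int
) -> pd.DataFrame:
    """Per-assignment (unsummed) contributions to the joint kernel.

    Each row assigns the empty, occupied/unrestricted and
    occupied/restricted site groups to their per-site outcome categories
    and carries the multinomial probability of that assignment together
    with the (Y1, Y2, S_next) value it produces.  Summing ``probability``
    over rows sharing (Y1, Y2, S_next) reproduces the kernel table; the
    unsummed rows are the enumeration view of the two-site illustration.
    """
    N = params.n_sites
    if not (0 <= A <= S <= N):
        raise ValueError(f"infeasible (S={S}, A={A}) for N={N}")
    table = site_event_table(probs, params)
    # per-group per-site category probabilities and their (y1, y2, occ) tags
    groups = {
        "empty": (table[[0, 3], 0], [(0, 0, 0), (0, 0, 1)]),
        "unrestricted": (table[[0, 2, 3, 5], 1],
                         [(0, 0, 0), (1, 0, 0), (0, 0, 1), (1, 0, 1)]),
        "restricted": (table[[0, 1, 3, 4], 2],
                       [(0, 0, 0), (0, 1, 0), (0, 0, 1), (0, 1, 1)]),
    }
    sizes = {"empty": N - S, "unrestricted": S - A, "restricted": A}

    def _multinomial(counts: np.ndarray, p: np.ndarray) -> float:
        from math import factorial

        coef = factorial(int(counts.sum()))
        for c in counts:
            coef //= factorial(int(c))
        return float(coef * np.prod(np.power(p, counts)))

    rows = []
    comps = {
        g: enumerate_assignments(sizes[g], len(groups[g][0])) for g in groups
    }
    for ce, cu, cr in product(comps["empty"], comps["unrestricted"], comps["restricted"]):
        prob = 1.0
        y1 = y2 = occ = 0
        for g, counts in (("empty", ce), ("unrestricted", cu), ("restricted", cr)):
            p, tags = groups[g]
            prob *= _multinomial(counts, p)
            for c, (t1, t2, to) in zip(counts, tags):
                y1 += c * t1
                y2 += c * t2
                occ += c * to
        rows.append(
            {
                "empty_counts": tuple(int(x) for x in ce),
                "unrestricted_counts": tuple(int(x) for x in cu),
                "restricted_counts": tuple(int(x) for x in cr),
                "Y1": y1,
                "Y2": y2,
                "S_next": occ,
                "probability": prob,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["Y1", "Y2", "S_next"], ignore_index=True
    )


def kernel_frame(kernel: JointKernel) -> pd.DataFrame:
    """Long-format view with columns (S, A, Y1, Y2, S_next, probability).

    Signal components not tracked by the kernel's mode are coded -1; for
    mode ``"total"`` the total success count is reported in Y1.
    """
    recs = []
    for (S, A) in kernel.pairs():
        flat = kernel.flat(S, A)
        for sig, row in zip(kernel.signal_values(S, A), flat):
            if kernel.mode == "full":
                y1, y2 = int(sig[0]), int(sig[1])
            elif kernel.mode == "unrestricted_only":
                y1, y2 = int(sig[0]), -1
            elif kernel.mode == "restricted_only":
                y1, y2 = -1, int(sig[0])
            elif kernel.mode == "total":
                y1, y2 = int(sig[0]), -1
            else:
                y1 = y2 = -1
            for s_next, p in enumerate(row):
                recs.append((S, A, y1, y2, s_next, float(p)))
    return pd.DataFrame(
        recs, columns=["S", "A", "Y1", "Y2", "S_next", "probability"]
    )


def kernel_to_csv(kernel: JointKernel, path: str | Path) -> None:
    kernel_frame(kernel).to_csv(path, index=False)
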