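"""Monte-Carlo trajectories and expected belief time paths.

Each replicate path starts from a chosen occupancy count and prior belief,
reads its action from a solved policy (nearest belief grid point), draws
the year's (signal, next occupancy) outcome from the *true* model's joint
kernel, and updates the belief by Bayes rule using whatever signal the
chosen mode makes observable.  Beliefs are carried exactly between years;
the grid is touched only for policy lookup, so discretization error does
not compound in the learning curves.

Randomness is a counter-based Philox stream keyed by ``(seed, path)`` —
one uniform per path-year, consumed by inverse-CDF sampling — so ensembles
are bit-for-bit reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .belief_mdp import BeliefPolicy
from .multisite import JointKernel

__all__ = ["TrajectoryEnsemble", "simulate", "expected_belief_paths"]


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Simulated occupancy, actions, signals and beliefs per path-year.

    ``S`` and ``B`` have one more column than ``A``/``Y1``/``Y2`` (year 0
    holds the initial state).  Signal components hidden by the mode are
    coded -1.
    """

    S: np.ndarray  #: (paths, years+1) occupied-site counts
    A: np.ndarray  #: (paths, years) restricted-site counts
    Y1: np.ndarray  #: (paths, years) unrestricted successes (-1 if hidden)
    Y2: np.ndarray  #: (paths, years) restricted successes (-1 if hidden)
    B: np.ndarray  #: (paths, years+1, 3) belief vectors
    true_model: int
    mode: str
    strategy: str
    seed: int
    n_paths: int
    n_years: int

    def to_frame(self) -> pd.DataFrame:
        """Long format (path, year, S, A, Y1, Y2, b1, b2, b3)."""
        P, Y = self.n_paths, self.n_years
        path = np.repeat(np.arange(P), Y)
        year = np.tile(np.arange(1, Y + 1), P)
        return pd.DataFrame(
            {
                "path": path,
                "year": year,
                "S": self.S[:, 1:].ravel(),
                "A": self.A.ravel(),
                "Y1": self.Y1.ravel(),
                "Y2": self.Y2.ravel(),
                "b1": self.B[:, 1:, 0].ravel(),
                "b2": self.B[:, 1:, 1].ravel(),
                "b3": self.B[:, 1:, 2].ravel(),
            }
        )


def _signal_of(kernel: JointKernel, flat_idx: np.ndarray, S: int, A: int):
    """Map flattened outcome indices back to (Y1, Y2, S_next) columns."""
    n1 = kernel.n_sites + 1
    sig, s_next = np.divmod(flat_idx, n1)
    if kernel.mode == "full":
        y1, y2 = np.divmod(sig, A + 1)
    elif kernel.mode == "unrestricted_only":
        y1, y2 = sig, np.full_like(sig, -1)
    elif kernel.mode == "restricted_only":
        y1, y2 = np.full_like(sig, -1), sig
    elif kernel.mode == "total":
        y1, y2 = sig, np.full_like(sig, -1)  # total count reported in Y1
    else:
        y1 = y2 = np.full_like(sig, -1)
    return y1, y2, s_next


def simulate(
    policy: BeliefPolicy,
    kernels: list[JointKernel],
    true_model: int,
    n_paths: int = 10000,
    n_years: int = 100,
    init_occupancy: int = 20,
    init_belief=None,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Sample replicate management paths under a chosen true model.

    ``kernels`` are the per-model kernels in the signal mode the policy was
    solved for; ``kernels[true_model]`` drives the system, and all three
    supply the likelihoods for the Bayes update.
    """
    mode = kernels[0].mode
    if {k.mode for k in kernels} != {mode}:
        raise ValueError("kernels must share one signal mode")
    if policy.strategy == "active" and policy.mode != mode:
        raise ValueError(
            f"policy was solved for signal mode {policy.mode!r}, "
            f"cannot update beliefs with mode {mode!r}"
        )
    N = kernels[0].n_sites
    if not 0 <= init_occupancy <= N:
        raise ValueError("init_occupancy outside 0..n_sites")
    init_belief = (
        np.full(3, 1.0 / 3.0) if init_belief is None else np.asarray(init_belief, float)
    )
    # per-(S, A): sampling CDF under the true model and model likelihoods
    cdf: dict[tuple[int, int], np.ndarray] = {}
    like: dict[tuple[int, int], np.ndarray] = {}
    for pair in kernels[0].pairs():
        flats = np.stack([k.flat(*pair).ravel() for k in kernels])  # (3, n_out)
        cdf[pair] = np.cumsum(flats[true_model])
        like[pair] = flats.T  # (n_out, 3)

    # one Philox stream per path, one uniform per path-year
    U = np.empty((n_paths, n_years))
    for p in range(n_paths):
        gen = np.random.Generator(np.random.Philox(key=[int(seed), p]))
        U[p] = gen.random(n_years)

    S = np.empty((n_paths, n_years + 1), dtype=np.int16)
    A = np.empty((n_paths, n_years), dtype=np.int16)
    Y1 = np.empty((n_paths, n_years), dtype=np.int16)
    Y2 = np.empty((n_paths, n_years), dtype=np.int16)
    B = np.empty((n_paths, n_years + 1, 3))
    S[:, 0] = init_occupancy
    B[:, 0] = init_belief

    for t in range(n_years):
        s_now = S[:, t].astype(np.int64)
        g = policy.grid.snap(B[:, t])
        a_now = np.minimum(policy.actions[s_now, g], s_now).astype(np.int64)
        A[:, t] = a_now
        out = np.empty(n_paths, dtype=np.int64)
        for pair in np.unique(np.stack([s_now, a_now], axis=1), axis=0):
            key = (int(pair[0]), int(pair[1]))
            sel = np.nonzero((s_now == key[0]) & (a_now == key[1]))[0]
            out[sel] = np.searchsorted(cdf[key], U[sel, t], side="right")
            out[sel] = np.minimum(out[sel], cdf[key].size - 1)
            y1, y2, s_next = _signal_of(kernels[0], out[sel], *key)
            Y1[sel, t], Y2[sel, t], S[sel, t + 1] = y1, y2, s_next
            post = B[sel, t] * like[key][out[sel]]
            total = post.sum(axis=1, keepdims=True)
            if np.any(total <= 0.0):
                raise ValueError(
                    "observation impossible under every model; kernels and "
                    "policy signal modes are inconsistent"
                )
            B[sel, t + 1] = post / total
    return TrajectoryEnsemble(
        S=S, A=A, Y1=Y1, Y2=Y2, B=B,
        true_model=true_model, mode=mode, strategy=policy.strategy,
        seed=int(seed), n_paths=n_paths, n_years=n_years,
    )


def expected_belief_paths(ensemble: TrajectoryEnsemble) -> pd.DataFrame:
    """Yearly mean belief vectors with Monte-Carlo standard errors."""
    mean = ensemble.B.mean(axis=0)
    se = ensemble.B.std(axis=0, ddof=1) / np.sqrt(ensemble.n_paths) \
        if ensemble.n_paths > 1 else np.zeros_like(mean)
    years = np.arange(ensemble.n_years + 1)
    return pd.DataFrame(
        {
            "year": years,
            "b1_mean": mean[:, 0], "b2_mean": mean[:, 1], "b3_mean": mean[:, 2],
            "b1_se": se[:, 0], "b2_se": se[:, 1], "b3_se": se[:, 2],
        }
    )


def ensemble_to_csv(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Persist long-format paths plus a config sidecar for provenance."""
    path = Path(path)
    ensemble.to_frame().to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta")
    sidecar.write_text(
        "\n".join(
            f"{k} = {getattr(ensemble, k)}"
            for k in ("true_model", "mode", "strategy", "seed",
                      "n_paths", "n_years")
        )
        + "\n"
    )
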