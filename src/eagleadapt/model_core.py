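"""Single-site occupancy/fledging probability model.

A nesting territory is either empty or occupied.  An occupied site may be
restricted to hikers (A=1) or left unrestricted (A=0); restricting an empty
site is not a meaningful action, so the site-level state/action space has
three points: (empty, unrestricted), (occupied, unrestricted) and
(occupied, restricted).  Each year an occupied site fledges successfully
with a probability that follows a logistic model in the arctic hare
abundance index ``h`` and a disturbance effect that applies only when the
site is unrestricted::

    p_r = logistic(beta_int + beta_hare * h)               # restricted
    p_u = logistic(beta_int + beta_dist + beta_hare * h)   # unrestricted

Next-year occupancy depends on this year's outcome: an empty site is
colonized with probability ``p_c``; an occupied site is re-occupied with
probability ``p_n`` after a failed season and ``p_s`` after a successful
one.  The joint distribution of the success signals and next-year occupancy
is the 6 x 3 site event table built by :func:`site_event_table`; its
marginals are the plain state-transition matrix (:func:`state_transition`)
and the outcome-conditional occupancy matrix
(:func:`signal_conditional_transition`).

Competing hypotheses about the strength of the disturbance effect are
expressed as alternative values of ``beta_dist`` (and, depending on which
success probability is taken as known, of ``beta_int``); the packaged
presets in :data:`PRESETS` hold the three standard uncertainty cases, each
with a no/moderate/strong disturbance model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "SiteParams",
    "SuccessProbs",
    "ModelSpec",
    "UncertaintyCase",
    "PRESETS",
    "get_preset",
    "success_probabilities",
    "site_event_table",
    "state_transition",
    "signal_conditional_transition",
    "degenerate_transition",
    "load_params",
    "save_params",
    "EVENT_ROWS",
    "EVENT_COLS",
]

#: Row labels of the site event table: (Y1, Y2, S_next).  Y1 flags a
#: successful fledging at an unrestricted site, Y2 at a restricted site.
EVENT_ROWS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (0, 1, 0),
    (1, 0, 0),
    (0, 0, 1),
    (0, 1, 1),
    (1, 0, 1),
)

#: Column labels: current (occupancy, restriction) of the site.
EVENT_COLS: tuple[str, ...] = (
    "empty_unrestricted",
    "occupied_unrestricted",
    "occupied_restricted",
)


@dataclass(frozen=True)
class SiteParams:
    """Demographic and management constants shared by every model.

    Parameters
    ----------
    p_c, p_n, p_s
        Colonization probability of an empty site, and re-occupancy
        probabilities after an unsuccessful / successful season.
    beta_int, beta_hare, beta_dist
        Logistic coefficients of the fledging-success model.
    hare
        Arctic hare abundance index (annual prey availability).
    n_sites
        Number of managed territories.
    alpha
        Utility exponent trading breeding success against hiker access.
    discount
        Per-year discount factor.
    """

    p_c: float = 0.2315
    p_n: float = 0.9427
    p_s: float = 0.9573
    beta_int: float = -0.75
    beta_hare: float = 0.06
    beta_dist: float = -0.2
    hare: float = 9.4
    n_sites: int = 25
    alpha: float = 0.85
    discount: float = 0.98

    def __post_init__(self) -> None:
        for name in ("p_c", "p_n", "p_s"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if not 0.0 <= self.discount < 1.0:
            raise ValueError(f"discount={self.discount} outside [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.hare < 0:
            raise ValueError("hare index must be >= 0")

    def with_(self, **kwargs) -> "SiteParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SuccessProbs:
    """Fledging success probabilities for one disturbance model."""

    p_u: float  #: success probability, unrestricted (possibly disturbed)
    p_r: float  #: success probability, restricted (undisturbed)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_u <= 1.0 and 0.0 <= self.p_r <= 1.0):
            raise ValueError("success probabilities must lie in [0, 1]")


def success_probabilities(
    params: SiteParams, model_beta_dist: float | None = None
) -> SuccessProbs:
    """Evaluate the logistic success model at the current hare level.

    ``model_beta_dist`` overrides ``params.beta_dist`` so that one shared
    parameter set can be evaluated under each candidate disturbance model.
    """
    bd = params.beta_dist if model_beta_dist is None else model_beta_dist
    eta = params.beta_int + params.beta_hare * params.hare
    return SuccessProbs(p_u=float(expit(eta + bd)), p_r=float(expit(eta)))


@dataclass(frozen=True)
class ModelSpec:
    """One candidate disturbance model (a row of an uncertainty case)."""

    label: str
    beta_int: float
    beta_dist: float
    beta_hare: float = 0.06

    def params(self, base: SiteParams) -> SiteParams:
        return base.with_(
            beta_int=self.beta_int,
            beta_dist=self.beta_dist,
            beta_hare=self.beta_hare,
        )

    def success_probs(self, base: SiteParams) -> SuccessProbs:
        return success_probabilities(self.params(base))


@dataclass(frozen=True)
class UncertaintyCase:
    """Three candidate disturbance models plus the matching best signal.

    ``signal_mode`` names the success signal that is informative about the
    uncertain parameter(s): unrestricted successes when ``p_r`` is known,
    restricted successes when ``p_u`` is known, and both counts when both
    are uncertain.
    """

    name: str
    models: tuple[ModelSpec, ModelSpec, ModelSpec]
    signal_mode: str

    def success_probs(self, base: SiteParams) -> list[SuccessProbs]:
        return [m.success_probs(base) for m in self.models]


def _case(name: str, rows: Sequence[tuple[float, float]], mode: str) -> UncertaintyCase:
    labels = ("no_disturbance", "moderate_disturbance", "strong_disturbance")
    models = tuple(
        ModelSpec(label=lab, beta_int=bi, beta_dist=bd)
        for lab, (bi, bd) in zip(labels, rows)
    )
    return UncertaintyCase(name=name, models=models, signal_mode=mode)


#: The three standard uncertainty regimes.  In ``pr_known`` the restricted
#: (undisturbed) success probability is treated as known and the candidate
#: models differ only in the disturbance coefficient.  In ``pu_known`` the
#: unrestricted probability is pinned (beta_int + beta_dist constant) and
#: the models differ in what restriction would achieve.  ``both_uncertain``
#: is the intermediate regime.
PRESETS: dict[str, UncertaintyCase] = {
    "pr_known": _case(
        "pr_known", [(-0.75, 0.0), (-0.75, -0.2), (-0.75, -0.6)], "unrestricted_only"
    ),
    "both_uncertain": _case(
        "both_uncertain", [(-0.85, 0.0), (-0.75, -0.2), (-0.65, -0.5)], "full"
    ),
    "pu_known": _case(
        "pu_known", [(-0.95, 0.0), (-0.75, -0.2), (-0.55, -0.4)], "restricted_only"
    ),
}


def get_preset(name: str) -> UncertaintyCase:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def site_event_table(probs: SuccessProbs, params: SiteParams) -> np.ndarray:
    """Joint distribution of (Y1, Y2, S_next) given the site's (S, A).

    Returns a 6 x 3 array whose rows follow :data:`EVENT_ROWS` and whose
    columns follow :data:`EVENT_COLS`.  Structural zeros: an empty site can
    produce no success signal; a restricted site cannot produce an
    unrestricted success (Y1) and vice versa.
    """
    pc, pn, ps = params.p_c, params.p_n, params.p_s
    pu, pr = probs.p_u, probs.p_r
    return np.array(
        [
            # (Y1, Y2, S+)      empty/unr          occupied/unr           occupied/restr
            [1.0 - pc, (1.0 - pu) * (1.0 - pn), (1.0 - pr) * (1.0 - pn)],  # (0,0,0)
            [0.0, 0.0, pr * (1.0 - ps)],                                   # (0,1,0)
            [0.0, pu * (1.0 - ps), 0.0],                                   # (1,0,0)
            [pc, (1.0 - pu) * pn, (1.0 - pr) * pn],                        # (0,0,1)
            [0.0, 0.0, pr * ps],                                           # (0,1,1)
            [0.0, pu * ps, 0.0],                                           # (1,0,1)
        ]
    )


def state_transition(probs: SuccessProbs, params: SiteParams) -> np.ndarray:
    """Occupancy transition matrix: signal-marginal of the event table.

    Rows are next-year occupancy (empty, occupied); columns follow
    :data:`EVENT_COLS`.  The occupied/unrestricted column is
    ``((1-p_u)(1-p_n) + p_u(1-p_s), (1-p_u)p_n + p_u p_s)`` and analogously
    with ``p_r`` when restricted.
    """
    table = site_event_table(probs, params)
    empty_next = table[:3].sum(axis=0)
    occ_next = table[3:].sum(axis=0)
    return np.vstack([empty_next, occ_next])


def signal_conditional_transition(params: SiteParams) -> np.ndarray:
    """Occupancy distribution conditional on this year's site outcome.

    Columns are (empty, unsuccessful), (occupied, unsuccessful),
    (occupied, successful); rows are next-year (empty, occupied).  Given
    the fledging outcome, the action carries no further information about
    next-year occupancy, which is why the success signal is the more
    informative conditioning variable.
    """
    pc, pn, ps = params.p_c, params.p_n, params.p_s
    return np.array([[1.0 - pc, 1.0 - pn, 1.0 - ps], [pc, pn, ps]])


def degenerate_transition(params: SiteParams) -> np.ndarray:
    """State transition in the no-learning limit ``p_n == p_s``.

    With equal re-occupancy probabilities the success probabilities cancel
    out of the occupancy dynamics entirely, so occupancy histories carry no
    information about the disturbance effect.
    """
    pc, pn = params.p_c, params.p_n
    return np.array([[1.0 - pc, 1.0 - pn, 1.0 - pn], [pc, pn, pn]])


# -- plain-text parameter files -------------------------------------------

_FIELDS = (
    "p_c",
    "p_n",
    "p_s",
    "beta_int",
    "beta_hare",
    "beta_dist",
    "hare",
    "n_sites",
    "alpha",
    "discount",
)


def load_params(path: str | Path) -> SiteParams:
    """Read a ``key = value`` parameter file into :class:`SiteParams`.

    Unknown keys raise; missing keys fall back to the packaged defaults.
    Lines starting with ``#`` and blank lines are ignored.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        values[key] = float(val.strip())
    if "n_sites" in values:
        n = values["n_sites"]
        if n != int(n):
            raise ValueError(f"n_sites must be an integer, got {n}")
        values["n_sites"] = int(n)
    return SiteParams(**values)


def save_params(params: SiteParams, path: str | Path) -> None:
    """Write a parameter set in the ``key = value`` exchange format."""
    d = asdict(params)
    lines = [f"{k} = {d[k]}" for k in _FIELDS]
    Path(path).write_text("\n".join(lines) + "\n")
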