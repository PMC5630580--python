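"""Bifurcation analysis: continuation, tipping points, separatrix, regime maps.

The control parameter of primary interest is the oxygen diffusivity
``alpha_O``, a proxy for turbulent mixing across a thermocline: a 1D sweep
produces the classic hysteresis picture (an anoxic branch that survives up
to a tipping point T1 and an oxic branch that survives down to T2 < T1),
and sweeping at many background-phosphorus values produces a 2D regime map
with five regions (oxic; bistable oxic/SB; bistable oxic/SB+PB; anoxic SB;
anoxic SB+PB).

Continuation reseeds each step from the previous equilibrium, with one
twist: every population is topped up to a small inoculum (default 10
cells/L, well below any equilibrium density of interest) so that branch
termination is an *invasibility* test. Without the inoculum a population
that has decayed to numerical zero could never re-invade and a branch could
be tracked past the point where it is ecologically unstable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import STATE_VARS, EcosystemState, RedoxModel
from .params import ModelParameters

__all__ = [
    "StateClass",
    "BranchPoint",
    "BifurcationBranch",
    "TippingPoints",
    "classify_state",
    "continue_branch",
    "find_tipping_points",
    "separatrix_scan",
    "bifurcation_grid_2d",
    "NoSeparatrixError",
]

#: population density below which a group counts as collapsed (cells/L)
EXTINCTION_THRESHOLD = 1.0

#: inoculum used when reseeding continuation steps (cells/L)
DEFAULT_INOCULUM = 10.0


class StateClass(enum.Enum):
    """Community composition of a steady state."""

    OXIC_CB = "oxic_cb"                  # cyanobacteria only
    ANOXIC_SB_ONLY = "anoxic_sb_only"    # sulfate reducers only
    ANOXIC_SB_PB = "anoxic_sb_pb"        # sulfate reducers + phototrophic S bacteria
    COLLAPSED = "collapsed"              # all groups extinct
    OTHER = "other"                      # any remaining pattern (incl. unconverged)

    @property
    def is_anoxic(self) -> bool:
        return self in (StateClass.ANOXIC_SB_ONLY, StateClass.ANOXIC_SB_PB)

    @property
    def macro(self) -> str:
        """Coarse regime: 'oxic', 'anoxic', 'collapsed' or 'other'.

        The two anoxic community forms (SB only vs SB+PB coexistence) are
        alternative faces of the same anoxic regime, exchanged through an
        interior transition that is not a tipping point.
        """
        if self is StateClass.OXIC_CB:
            return "oxic"
        if self.is_anoxic:
            return "anoxic"
        if self is StateClass.COLLAPSED:
            return "collapsed"
        return "other"


class NoSeparatrixError(RuntimeError):
    """Both scan endpoints reached the same attractor: nothing to bisect."""


def classify_state(
    state: EcosystemState, threshold: float = EXTINCTION_THRESHOLD
) -> StateClass:
    """Map a converged steady state to a :class:`StateClass`.

    A group is "present" when its density exceeds *threshold* (cells/L).
    Patterns outside the four canonical ones (e.g. CB coexisting with SB)
    are reported as OTHER, never silently relabelled.
    """
    cb = state.N_CB > threshold
    pb = state.N_PB > threshold
    sb = state.N_SB > threshold
    if cb and not pb and not sb:
        return StateClass.OXIC_CB
    if sb and not cb and not pb:
        return StateClass.ANOXIC_SB_ONLY
    if sb and pb and not cb:
        return StateClass.ANOXIC_SB_PB
    if not cb and not pb and not sb:
        return StateClass.COLLAPSED
    return StateClass.OTHER


@dataclass(frozen=True)
class BranchPoint:
    control_value: float
    steady_state: EcosystemState
    state_class: StateClass
    converged: bool


@dataclass
class BifurcationBranch:
    """An equilibrium branch tracked by continuation.

    ``points`` contains only converged steady states of the tracked class,
    in sweep order; ``terminal_control`` is the control value of the last
    point before the branch lost stability (the end of the sweep range when
    it never did).
    """

    control_name: str
    direction: str  # "increasing" | "decreasing"
    points: list = field(default_factory=list)
    terminal_control: Optional[float] = None
    terminated_by: Optional[str] = None  # "class_change" | "non_convergence" | None

    @property
    def branch_class(self) -> Optional[StateClass]:
        return self.points[0].state_class if self.points else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = {"control_value": pt.control_value}
            row.update(pt.steady_state.to_dict())
            row["state_class"] = pt.state_class.value
            rows.append(row)
        return pd.DataFrame(rows, columns=["control_value", *STATE_VARS, "state_class"])


@dataclass(frozen=True)
class TippingPoints:
    T1: Optional[float]
    T2: Optional[float]
    hysteresis_width: float
    bistable: bool


def _with_inoculum(state: EcosystemState, inoculum: float) -> EcosystemState:
    d = state.to_dict()
    for name in ("N_CB", "N_PB", "N_SB"):
        d[name] = max(d[name], inoculum)
    return EcosystemState(**d)


def continue_branch(
    params: ModelParameters,
    control_name: str,
    control_values: Sequence[float],
    seed_state: EcosystemState,
    inoculum: float = DEFAULT_INOCULUM,
    tol: Optional[float] = None,
    t_max: float = 1e6,
    track: str = "macro",
) -> BifurcationBranch:
    """Track an equilibrium branch over a sweep of a control parameter.

    ``control_values`` must be strictly monotone; the steady state found at
    each value (seeded from the previous one, populations topped up to
    *inoculum*) becomes the seed for the next. The branch terminates when
    the converged state's class changes from the class established at the
    first control value, or when convergence fails within ``t_max`` hours.
    With ``track='macro'`` (default) the comparison uses the coarse
    oxic/anoxic/collapsed regime, so the anoxic branch survives the interior
    hand-off between its SB-only and SB+PB forms; ``track='exact'`` compares
    full :class:`StateClass` labels.

    Raises if the seed fails to converge at the first control value.
    """
    if track not in ("macro", "exact"):
        raise ValueError(f"track must be 'macro' or 'exact', got {track!r}")
    cv = np.asarray(control_values, dtype=float)
    if len(cv) < 2:
        raise ValueError("need at least two control values")
    d = np.diff(cv)
    if np.all(d > 0):
        direction = "increasing"
    elif np.all(d < 0):
        direction = "decreasing"
    else:
        raise ValueError("control values must be strictly monotone")
    if control_name not in params.to_dict():
        raise KeyError(f"unknown control parameter {control_name!r}")

    branch = BifurcationBranch(control_name=control_name, direction=direction)
    seed = seed_state
    for i, value in enumerate(cv):
        model = RedoxModel(params.replace(**{control_name: value}))
        state, converged = model.find_steady_state(
            _with_inoculum(seed, inoculum), tol=tol, t_max=t_max
        )
        if not converged:
            if i == 0:
                raise RuntimeError(
                    f"seed state failed to converge at {control_name}={value:g}"
                )
            branch.terminated_by = "non_convergence"
            break
        state_class = classify_state(state)
        key = state_class.macro if track == "macro" else state_class
        if i == 0:
            branch_key = key
        elif key != branch_key:
            branch.terminated_by = "class_change"
            break
        branch.points.append(BranchPoint(value, state, state_class, converged))
        seed = state
    branch.terminal_control = branch.points[-1].control_value if branch.points else None
    return branch


def find_tipping_points(
    up_branch: BifurcationBranch, down_branch: BifurcationBranch
) -> TippingPoints:
    """Tipping points from a pair of opposite-direction sweeps.

    ``T1`` is where the anoxic branch (tracked under increasing control)
    loses stability; ``T2`` is where the oxic branch (tracked under
    decreasing control) loses it. The hysteresis width is ``T1 - T2`` when
    the system is bistable in between, else 0 with ``bistable=False``.
    """
    if up_branch.direction != "increasing" or down_branch.direction != "decreasing":
        raise ValueError("expected one increasing and one decreasing branch")
    if not up_branch.points or not down_branch.points:
        raise ValueError("branches must contain at least one converged point")
    up_range = (up_branch.points[0].control_value, up_branch.terminal_control)
    down_range = (down_branch.terminal_control, down_branch.points[0].control_value)
    if up_range[1] < down_range[0] or down_range[1] < up_range[0]:
        raise ValueError("branch sweep ranges do not overlap")

    T1 = up_branch.terminal_control
    T2 = down_branch.terminal_control
    width = T1 - T2
    if (
        width > 0
        and up_branch.branch_class.macro != down_branch.branch_class.macro
    ):
        return TippingPoints(T1=T1, T2=T2, hysteresis_width=width, bistable=True)
    return TippingPoints(T1=T1, T2=T2, hysteresis_width=0.0, bistable=False)


#: other initial conditions of the 1D bifurcation scan (cells/L and uM):
#: all but the cyanobacterial density are held fixed while N_CB varies
SEPARATRIX_BASE_INIT = {
    "N_PB": 1e8,
    "N_SB": 1e8,
    "S_O": 250.0,
    "S_R": 350.0,
    "O": 150.0,
    "P": 9.5,
}


def _attractor_is_oxic(
    params: ModelParameters, n_cb: float, other_inits: dict, tol, t_max
) -> bool:
    model = RedoxModel(params)
    state0 = EcosystemState(N_CB=n_cb, **other_inits)
    state, converged = model.find_steady_state(state0, tol=tol, t_max=t_max)
    cls = classify_state(state)
    if not converged and cls is StateClass.OTHER:
        raise RuntimeError(f"no attractor reached from N_CB={n_cb:g}")
    return cls is StateClass.OXIC_CB


def separatrix_scan(
    params: ModelParameters,
    n_cb_low: float = 1.0,
    n_cb_high: float = 1e12,
    other_inits: Optional[dict] = None,
    rel_tol: float = 0.05,
    tol: Optional[float] = None,
    t_max: float = 1e6,
) -> float:
    """Boundary initial cyanobacterial density between the two basins.

    Bisects (in log density) between ``n_cb_low`` and ``n_cb_high`` with all
    other initial conditions fixed (default: the 1D-bifurcation scan values
    in :data:`SEPARATRIX_BASE_INIT`), until the bracket's ratio is within
    ``1 + rel_tol``. Raises :class:`NoSeparatrixError` when both endpoints
    reach the same attractor (monostable case).
    """
    other = dict(SEPARATRIX_BASE_INIT if other_inits is None else other_inits)
    lo_oxic = _attractor_is_oxic(params, n_cb_low, other, tol, t_max)
    hi_oxic = _attractor_is_oxic(params, n_cb_high, other, tol, t_max)
    if lo_oxic == hi_oxic:
        raise NoSeparatrixError(
            f"both endpoints reach the same ({'oxic' if lo_oxic else 'anoxic'}) "
            "attractor; system not bistable along this initial-condition line"
        )
    lo, hi = float(n_cb_low), float(n_cb_high)
    while hi / lo > 1.0 + rel_tol:
        mid = np.sqrt(lo * hi)
        if _attractor_is_oxic(params, mid, other, tol, t_max) == hi_oxic:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


# -- 2D regime map ------------------------------------------------------------

#: region labels of the 2D map
REGION_OXIC = "oxic"
REGION_BISTABLE_SB = "bistable_oxic_sb"
REGION_BISTABLE_SB_PB = "bistable_oxic_sb_pb"
REGION_ANOXIC_SB = "anoxic_sb"
REGION_ANOXIC_SB_PB = "anoxic_sb_pb"
REGION_OTHER = "other"


def _pair_to_region(up_cls: StateClass, down_cls: StateClass) -> str:
    """Label a grid cell from the increasing-sweep (anoxic-seeded) and
    decreasing-sweep (oxic-seeded) outcomes at that cell.

    At exact region borders the increasing-sweep outcome decides (documented
    tie-break: when both sweeps land on the same attractor the cell is
    labelled by that attractor; an OTHER pattern in either sweep labels the
    cell OTHER).
    """
    if up_cls is StateClass.OTHER or down_cls is StateClass.OTHER:
        return REGION_OTHER
    if up_cls.is_anoxic and down_cls is StateClass.OXIC_CB:
        return (
            REGION_BISTABLE_SB
            if up_cls is StateClass.ANOXIC_SB_ONLY
            else REGION_BISTABLE_SB_PB
        )
    if up_cls is StateClass.OXIC_CB:
        return REGION_OXIC
    if up_cls.is_anoxic:  # down sweep also anoxic
        return (
            REGION_ANOXIC_SB
            if up_cls is StateClass.ANOXIC_SB_ONLY
            else REGION_ANOXIC_SB_PB
        )
    return REGION_OTHER


#: canonical seed states used for the two sweeps of the regime map
ANOXIC_SEED = EcosystemState(
    N_CB=5e1, N_PB=1e7, N_SB=1e7, S_O=300.0, S_R=300.0, O=10.0, P=10.0
)
OXIC_SEED = EcosystemState(
    N_CB=1e8, N_PB=1e2, N_SB=1e2, S_O=500.0, S_R=50.0, O=300.0, P=4.0
)


def bifurcation_grid_2d(
    params: ModelParameters,
    alpha_O_range: Tuple[float, float] = (1e-5, 1e-2),
    P_b_range: Tuple[float, float] = (1.0, 10.0),
    resolution: Tuple[int, int] = (50, 50),
    inoculum: float = DEFAULT_INOCULUM,
    tol: Optional[float] = None,
    t_max: float = 1e6,
) -> pd.DataFrame:
    """Regime map over background phosphorus (linear) x oxygen diffusivity
    (logarithmic).

    For each ``P_b``, an increasing-``alpha_O`` continuation seeded from an
    anoxic community and a decreasing one seeded from an oxic community are
    run; each grid cell is labelled from the two outcomes at that cell via
    :func:`_pair_to_region`. Returns a long-format frame with columns
    ``P_b``, ``alpha_O``, ``label``. Deterministic: no randomness anywhere.
    """
    n_p, n_a = resolution
    if n_p < 2 or n_a < 2:
        raise ValueError("resolution must be >= 2 per axis")
    p_values = np.linspace(P_b_range[0], P_b_range[1], n_p)
    a_values = np.logspace(np.log10(alpha_O_range[0]), np.log10(alpha_O_range[1]), n_a)

    rows = []
    for p_b in p_values:
        base = params.replace(P_b=float(p_b))
        up_cls = _sweep_classes(base, a_values, ANOXIC_SEED, inoculum, tol, t_max)
        down_cls = _sweep_classes(base, a_values[::-1], OXIC_SEED, inoculum, tol, t_max)[::-1]
        for a, uc, dc in zip(a_values, up_cls, down_cls):
            rows.append(
                {"P_b": float(p_b), "alpha_O": float(a), "label": _pair_to_region(uc, dc)}
            )
    return pd.DataFrame(rows)


def _sweep_classes(params, a_values, seed_state, inoculum, tol, t_max):
    """Steady-state class at each control value of a full sweep.

    Unlike :func:`continue_branch` the sweep does not stop at a class
    change: after the tracked attractor disappears the trajectory simply
    lands on the remaining attractor, which is exactly what the regime map
    needs. Unconverged cells are labelled OTHER.
    """
    classes = []
    seed = seed_state
    for a in a_values:
        model = RedoxModel(params.replace(alpha_O=float(a)))
        state, converged = model.find_steady_state(
            _with_inoculum(seed, inoculum), tol=tol, t_max=t_max
        )
        classes.append(classify_state(state) if converged else StateClass.OTHER)
        if converged:
            seed = state
    return classes


def attractor_census(
    params: ModelParameters,
    initial_states: Sequence[EcosystemState],
    tol: Optional[float] = None,
    t_max: float = 1e6,
    inoculum: float = DEFAULT_INOCULUM,
) -> str:
    """Brute-force region label from a multi-start attractor census.

    Runs the model to steady state from every provided initial condition
    and derives the region label from the set of attractor classes found.
    Each converged state is then stabilized against invasion: extinct
    populations are topped up to *inoculum* and the system relaxed again
    until the class repeats, so that states a rare immigrant would
    overturn (reachable only because a population hit numerical zero
    during a transient) are not counted as attractors. Used as an
    independent oracle for :func:`bifurcation_grid_2d`.
    """
    model = RedoxModel(params)
    found = set()
    for s in initial_states:
        state, converged = model.find_steady_state(s, tol=tol, t_max=t_max)
        if not converged:
            continue
        cls = classify_state(state)
        for _ in range(3):  # invasion-stabilization rounds
            state, converged = model.find_steady_state(
                _with_inoculum(state, inoculum), tol=tol, t_max=t_max
            )
            if not converged:
                break
            new_cls = classify_state(state)
            if new_cls is cls:
                break
            cls = new_cls
        if converged:
            found.add(cls)
    oxic = StateClass.OXIC_CB in found
    anoxic = {c for c in found if c.is_anoxic}
    if oxic and anoxic:
        return (
            REGION_BISTABLE_SB
            if anoxic == {StateClass.ANOXIC_SB_ONLY}
            else REGION_BISTABLE_SB_PB
        )
    if oxic:
        return REGION_OXIC
    if anoxic == {StateClass.ANOXIC_SB_ONLY}:
        return REGION_ANOXIC_SB
    if StateClass.ANOXIC_SB_PB in anoxic:
        return REGION_ANOXIC_SB_PB
    return REGION_OTHER
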