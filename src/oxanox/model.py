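"""The microbial redox ecosystem ODE model.

Seven coupled ordinary differential equations describe a well-mixed box:
three bacterial populations (cyanobacteria CB, phototrophic sulfur bacteria
PB, sulfate-reducing bacteria SB) and four substrates (oxidized sulfur S_O,
reduced sulfur S_R, oxygen O, phosphorus P).

Population dynamics
    dN_CB/dt = g_CB(P) h_CB(S_R) N_CB - m_CB N_CB
    dN_PB/dt = g_PB(P, S_R) h_PB(O) N_PB - m_PB N_PB
    dN_SB/dt = g_SB(P, S_O) h_SB(O) N_SB - m_SB N_SB

Substrate dynamics
    dS_O/dt = (1/y_PB_S) g_PB h_PB N_PB - (1/y_SB_S) g_SB h_SB N_SB
              + c O S_R + alpha_S (S_O_b - S_O)
    dS_R/dt = -(1/y_PB_S) g_PB h_PB N_PB + (1/y_SB_S) g_SB h_SB N_SB
              - c O S_R + alpha_S (S_R_b - S_R)
    dO/dt   = p_CB g_CB h_CB N_CB - c O S_R + alpha_O (O_b - O)
    dP/dt   = -(1/y_CB_P) g_CB h_CB N_CB - (1/y_PB_P) g_PB h_PB N_PB
              - (1/y_SB_P) g_SB h_SB N_SB + alpha_P (P_b - P)

Growth follows Monod kinetics (multiplicative when two substrates limit);
inhibition follows the Haldane form 1/(1 + X/H), which halves the growth
rate when the inhibitor concentration X equals the half-inhibition
constant H. Biologically: sulfide inhibits cyanobacteria, oxygen inhibits
both groups of anaerobic sulfur bacteria, and this reciprocal inhibition is
what creates alternative oxic/anoxic stable states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParameters, default_parameters

__all__ = [
    "STATE_VARS",
    "EcosystemState",
    "SimulationResult",
    "IntegrationError",
    "monod_growth",
    "haldane_inhibition",
    "RedoxModel",
]

#: canonical ordering of the seven state variables
STATE_VARS = ("N_CB", "N_PB", "N_SB", "S_O", "S_R", "O", "P")

#: relative clipping tolerance for tiny negative excursions of RK4 steps
_CLIP_REL = 1e-9

#: per-variable scales used in the scaled steady-state criterion
#: (1 cell/L for populations, 1e-3 uM for substrates)
_STEADY_SCALES = np.array([1.0, 1.0, 1.0, 1e-3, 1e-3, 1e-3, 1e-3])


class IntegrationError(RuntimeError):
    """Raised when numerical integration fails (NaN/overflow or a negative
    excursion too large to be a rounding artefact)."""


@dataclass(frozen=True)
class EcosystemState:
    """The seven state variables: populations in cells/L, substrates in uM."""

    N_CB: float
    N_PB: float
    N_SB: float
    S_O: float
    S_R: float
    O: float
    P: float

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"state variable {name!r} must be finite, got {v}")
            if v < 0.0:
                raise ValueError(f"state variable {name!r} must be >= 0, got {v}")
            object.__setattr__(self, name, v)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "EcosystemState":
        x = np.asarray(x, dtype=float)
        if x.shape != (7,):
            raise ValueError(f"expected 7 state components, got shape {x.shape}")
        return cls(**dict(zip(STATE_VARS, x)))

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in STATE_VARS}

    @classmethod
    def from_dict(cls, d: dict) -> "EcosystemState":
        unknown = set(d) - set(STATE_VARS)
        if unknown:
            raise KeyError(f"unknown state variable(s): {sorted(unknown)}")
        missing = set(STATE_VARS) - set(d)
        if missing:
            raise KeyError(f"missing state variable(s): {sorted(missing)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "EcosystemState":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a mapping of state variables")
        return cls.from_dict(d)

    def to_file(self, path: Union[str, Path]) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class SimulationResult:
    """Trajectory of a single simulation.

    ``times`` (h) is strictly increasing; ``states`` has one row per output
    time in the :data:`STATE_VARS` order. ``max_residual`` is the scaled
    derivative norm at the final state, and ``converged`` says whether it is
    below the steady-state tolerance in force when the result was produced.
    """

    times: np.ndarray
    states: np.ndarray
    converged: bool
    max_residual: float
    method: str

    @property
    def final_state(self) -> EcosystemState:
        return EcosystemState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Plot populations (log scale, left axis) and substrates (right)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for i, name in enumerate(STATE_VARS[:3]):
            ax.semilogy(self.times, np.maximum(self.states[:, i], 1e-2), label=name)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("population (cells/L)")
        ax2 = ax.twinx()
        for i, name in enumerate(STATE_VARS[3:], start=3):
            ax2.plot(self.times, self.states[:, i], "--", label=name)
        ax2.set_ylabel("concentration (uM)")
        h1, l1 = ax.get_legend_handles_labels()
        h2, l2 = ax2.get_legend_handles_labels()
        ax.legend(h1 + h2, l1 + l2, fontsize=8, ncol=2)
        return ax


def monod_growth(
    g_max: float,
    X: float,
    K_X: float,
    Y: Optional[float] = None,
    K_Y: Optional[float] = None,
) -> float:
    """Monod growth rate, multiplicative when two substrates limit.

    Returns ``g_max * X/(K_X+X)`` for a single substrate, or
    ``g_max * X/(K_X+X) * Y/(K_Y+Y)`` when ``Y``/``K_Y`` are given.
    """
    if g_max <= 0:
        raise ValueError(f"g_max must be > 0, got {g_max}")
    if K_X <= 0:
        raise ValueError(f"half-saturation constant K_X must be > 0, got {K_X}")
    if X < 0:
        raise ValueError(f"substrate concentration X must be >= 0, got {X}")
    rate = g_max * X / (K_X + X)
    if (Y is None) != (K_Y is None):
        raise ValueError("Y and K_Y must be given together")
    if Y is not None:
        if K_Y <= 0:
            raise ValueError(f"half-saturation constant K_Y must be > 0, got {K_Y}")
        if Y < 0:
            raise ValueError(f"substrate concentration Y must be >= 0, got {Y}")
        rate *= Y / (K_Y + Y)
    return rate


def haldane_inhibition(X: float, H: float) -> float:
    """Haldane inhibition factor ``1/(1 + X/H)``.

    Equals 1 with no inhibitor and 0.5 at ``X == H`` (the half-inhibition
    constant); strictly decreasing in X with range (0, 1].
    """
    if H <= 0:
        raise ValueError(f"half-inhibition constant H must be > 0, got {H}")
    if X < 0:
        raise ValueError(f"inhibitor concentration X must be >= 0, got {X}")
    return 1.0 / (1.0 + X / H)


def _rhs(x: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Right-hand side of the seven ODEs (scalar arithmetic, hot path)."""
    N_CB, N_PB, N_SB, S_O, S_R, O, P = x

    # realized specific growth rates (Monod * Haldane)
    mu_CB = p.g_max_CB * (P / (p.K_CB_P + P)) / (1.0 + S_R / p.H_CB_SR)
    mu_PB = (
        p.g_max_PB
        * (P / (p.K_PB_P + P))
        * (S_R / (p.K_PB_SR + S_R))
        / (1.0 + O / p.H_PB_O)
    )
    mu_SB = (
        p.g_max_SB
        * (P / (p.K_SB_P + P))
        * (S_O / (p.K_SB_SO + S_O))
        / (1.0 + O / p.H_SB_O)
    )

    growth_CB = mu_CB * N_CB
    growth_PB = mu_PB * N_PB
    growth_SB = mu_SB * N_SB
    oxidation = p.c * O * S_R

    dN_CB = growth_CB - p.m_CB * N_CB
    dN_PB = growth_PB - p.m_PB * N_PB
    dN_SB = growth_SB - p.m_SB * N_SB
    dS_O = (
        growth_PB / p.y_PB_S
        - growth_SB / p.y_SB_S
        + oxidation
        + p.alpha_S * (p.S_O_b - S_O)
    )
    dS_R = (
        -growth_PB / p.y_PB_S
        + growth_SB / p.y_SB_S
        - oxidation
        + p.alpha_S * (p.S_R_b - S_R)
    )
    dO = p.p_CB * growth_CB - oxidation + p.alpha_O * (p.O_b - O)
    dP = (
        -growth_CB / p.y_CB_P
        - growth_PB / p.y_PB_P
        - growth_SB / p.y_SB_P
        + p.alpha_P * (p.P_b - P)
    )
    return np.array([dN_CB, dN_PB, dN_SB, dS_O, dS_R, dO, dP])


def _scaled_residual(x: np.ndarray, dx: np.ndarray) -> float:
    """max_i |dx_i| / (|x_i| + scale_i) — the steady-state criterion."""
    return float(np.max(np.abs(dx) / (np.abs(x) + _STEADY_SCALES)))


class RedoxModel:
    """The ecosystem model bound to one parameter set.

    Parameters
    ----------
    params : ModelParameters, optional
        Defaults to the package's calibrated default set.

    Examples
    --------
    >>> from oxanox import RedoxModel, EcosystemState
    >>> model = RedoxModel()
    >>> state0 = EcosystemState(N_CB=5e1, N_PB=1e7, N_SB=1e7,
    ...                         S_O=300, S_R=300, O=10, P=10)
    >>> result = model.simulate(state0, t_end=5000)
    >>> result.final_state.O < 50  # anoxic outcome
    True
    """

    #: default steady-state tolerance on the scaled derivative norm
    steady_tol: float = 1e-8

    def __init__(self, params: Optional[ModelParameters] = None):
        self.params = params if params is not None else default_parameters()

    def __repr__(self) -> str:
        p = self.params
        return (
            f"RedoxModel(alpha_O={p.alpha_O:g}, P_b={p.P_b:g}, "
            f"O_b={p.O_b:g}, alpha_S={p.alpha_S:g})"
        )

    # -- derivatives ----------------------------------------------------------

    def derivatives(self, state) -> EcosystemState:
        """Time derivatives (per hour) of all seven state variables.

        Accepts an :class:`EcosystemState` or a length-7 array in the
        :data:`STATE_VARS` order; returns an object of the same kind
        (derivative components may be negative).
        """
        if isinstance(state, EcosystemState):
            return _Derivative(*_rhs(state.to_array(), self.params))
        x = np.asarray(state, dtype=float)
        if x.shape != (7,):
            raise ValueError(f"expected 7 state components, got shape {x.shape}")
        if np.any(x < 0):
            raise ValueError("state components must be >= 0")
        return _rhs(x, self.params)

    # -- integration ----------------------------------------------------------

    def simulate(
        self,
        state0,
        t_end: float,
        method: str = "adaptive",
        dt: Optional[float] = None,
        n_out: int = 200,
        steady_tol: Optional[float] = None,
    ) -> SimulationResult:
        """Integrate the model from ``state0`` to ``t_end``.

        ``method='rk4'`` uses a fixed-step classic 4th-order Runge-Kutta
        scheme (``dt`` defaults to a stability pre-check value);
        ``method='adaptive'`` uses LSODA (stiff-capable, adaptive step).
        Infinitesimal negative excursions (relative magnitude below 1e-9)
        are clipped to zero; larger negatives raise IntegrationError.
        """
        if t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {t_end}")
        x0 = self._as_array(state0)
        tol = self.steady_tol if steady_tol is None else steady_tol

        if method == "rk4":
            times, states = self._integrate_rk4(x0, t_end, dt, n_out)
        elif method == "adaptive":
            times, states = self._integrate_adaptive(x0, t_end, n_out)
        else:
            raise ValueError(f"unknown method {method!r}; use 'rk4' or 'adaptive'")

        resid = _scaled_residual(states[-1], _rhs(states[-1], self.params))
        return SimulationResult(
            times=times,
            states=states,
            converged=resid < tol,
            max_residual=resid,
            method=method,
        )

    def find_steady_state(
        self,
        state0,
        tol: Optional[float] = None,
        t_max: float = 1e6,
        method: str = "adaptive",
        chunk: float = 2000.0,
    ):
        """Integrate until the scaled derivative norm drops below ``tol``.

        Returns ``(EcosystemState, converged)``. Non-convergence within
        ``t_max`` hours is reported via the flag, never as an exception.
        """
        tol = self.steady_tol if tol is None else tol
        if tol <= 0:
            raise ValueError(f"tol must be > 0, got {tol}")
        x = self._as_array(state0)
        t = 0.0
        resid = _scaled_residual(x, _rhs(x, self.params))
        while resid >= tol and t < t_max:
            span = min(chunk, t_max - t)
            if method == "rk4":
                _, states = self._integrate_rk4(x, span, None, 2)
            else:
                _, states = self._integrate_adaptive(x, span, 2)
            x = states[-1]
            t += span
            resid = _scaled_residual(x, _rhs(x, self.params))
            # widen the chunk as the transient dies off (slow modes near
            # transcritical boundaries can take ~1e6 h to relax)
            chunk = min(chunk * 2.0, 256000.0)
        return EcosystemState.from_array(x), bool(resid < tol)

    # -- internals ------------------------------------------------------------

    @staticmethod
    def _as_array(state0) -> np.ndarray:
        if isinstance(state0, EcosystemState):
            return state0.to_array()
        x0 = np.asarray(state0, dtype=float)
        if x0.shape != (7,):
            raise ValueError(f"expected 7 state components, got shape {x0.shape}")
        if np.any(x0 < 0):
            raise ValueError("initial state components must be >= 0")
        return x0.copy()

    def stable_dt(self) -> float:
        """A conservative fixed step from the fastest linear rate present."""
        p = self.params
        # fastest per-hour relaxation scales in the model: growth, mortality,
        # diffusive exchange, and the oxidation term at background levels
        fastest = max(
            p.g_max_CB, p.g_max_PB, p.g_max_SB,
            p.m_CB, p.m_PB, p.m_SB,
            p.alpha_S, p.alpha_O, p.alpha_P,
            p.c * max(p.O_b, 1.0) * 10.0,
            p.c * max(p.S_R_b, 1.0) * 10.0,
        )
        return min(1.0, 0.2 / fastest)

    def _clip(self, x: np.ndarray, t: float) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"integration produced NaN/overflow at t={t:g} h")
        neg = x < 0
        if np.any(neg):
            scale = np.maximum(np.abs(x).max(), 1.0)
            worst = float(-x[neg].min())
            if worst > _CLIP_REL * scale:
                raise IntegrationError(
                    f"state went negative (magnitude {worst:g}) at t={t:g} h; "
                    "step size too large"
                )
            x = np.where(neg, 0.0, x)
        return x

    def _integrate_rk4(self, x0, t_end, dt, n_out):
        p = self.params
        if dt is None:
            dt = self.stable_dt()
        if dt <= 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        n_steps = max(1, int(math.ceil(t_end / dt)))
        dt = t_end / n_steps
        n_out = max(2, min(n_out, n_steps + 1))
        out_idx = np.unique(np.round(np.linspace(0, n_steps, n_out)).astype(int))
        times = out_idx * dt
        states = np.empty((len(out_idx), 7))
        x = x0.copy()
        j = 0
        if out_idx[0] == 0:
            states[0] = x
            j = 1
        for i in range(1, n_steps + 1):
            k1 = _rhs(x, p)
            k2 = _rhs(self._clip(x + 0.5 * dt * k1, i * dt), p)
            k3 = _rhs(self._clip(x + 0.5 * dt * k2, i * dt), p)
            k4 = _rhs(self._clip(x + dt * k3, i * dt), p)
            x = self._clip(x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), i * dt)
            if j < len(out_idx) and i == out_idx[j]:
                states[j] = x
                j += 1
        return times, states

    def _integrate_adaptive(self, x0, t_end, n_out):
        p = self.params
        t_eval = np.linspace(0.0, t_end, max(2, n_out))
        sol = solve_ivp(
            lambda t, x: _rhs(x, p),
            (0.0, t_end),
            x0,
            method="LSODA",
            t_eval=t_eval,
            rtol=1e-8,
            atol=np.array([1e-6, 1e-6, 1e-6, 1e-9, 1e-9, 1e-9, 1e-9]),
        )
        if not sol.success:
            raise IntegrationError(f"adaptive integration failed: {sol.message}")
        states = sol.y.T.copy()
        for i in range(len(states)):
            states[i] = self._clip(states[i], sol.t[i])
        return sol.t, states


class _Derivative(EcosystemState):
    """An EcosystemState-shaped derivative; components may be negative."""

    def __post_init__(self) -> None:  # skip the non-negativity check
        for name in STATE_VARS:
            object.__setattr__(self, name, float(getattr(self, name)))
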