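"""Reaction kinetics of the cortical excitability circuit.

Three coupled fields live on the membrane: active Rho (``RT``),
inactive membrane Rho (``RD``) and dynamic cortical F-actin (``F``).
The full model adds a cytoplasmic inactive pool (``RDc``) that
exchanges with the membrane at a rate controlled by the small volume
ratio ``eta``; sending ``eta -> 0`` with ``RDc = RD0`` recovers the
reduced model with net delivery rate ``k5 = k5_star * RD0``.

Rho kinetics::

    R = [k0 + alpha*k1*RT^3 / (1 + k2*RT^2)] * RD
        - [k3 + k4*(1 + beta)*F] * RT

F-actin kinetics (W is the mean-1 noise field, W=1 deterministically)::

    dF/dt = k7 + k8*RT^2 / (1 + k9*RT^2) - k10*W*F
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import FullModelParams, ModelParams

__all__ = [
    "State",
    "FullState",
    "SteadyState",
    "reaction_rate",
    "actin_rate",
    "rhs_reduced",
    "rhs_full",
    "uniform_steady_state",
    "reduce_full_params",
]

ArrayLike = Union[float, np.ndarray]


@dataclass
class State:
    """Field snapshot of the reduced model on a 2D lattice."""

    RT: np.ndarray
    RD: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        if not (self.RT.shape == self.RD.shape == self.F.shape):
            raise ValueError("state fields must share one shape")

    @property
    def shape(self):
        return self.RT.shape

    def copy(self) -> "State":
        return State(self.RT.copy(), self.RD.copy(), self.F.copy())

    def as_array(self) -> np.ndarray:
        return np.stack([self.RT, self.RD, self.F])


@dataclass
class FullState(State):
    """Field snapshot of the full model (adds the cytoplasmic pool)."""

    RDc: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.RDc is None or self.RDc.shape != self.RT.shape:
            raise ValueError("RDc must be given with the same shape")

    def copy(self) -> "FullState":
        return FullState(self.RT.copy(), self.RD.copy(), self.F.copy(),
                         self.RDc.copy())

    def as_array(self) -> np.ndarray:
        return np.stack([self.RT, self.RD, self.F, self.RDc])


@dataclass(frozen=True)
class SteadyState:
    """A spatially uniform fixed point of the reduced kinetics."""

    RT_ss: float
    RD_ss: float
    F_ss: float
    residual: float

    def as_tuple(self):
        return (self.RT_ss, self.RD_ss, self.F_ss)


def _check_nonneg(**fields) -> None:
    for name, value in fields.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"negative concentration in {name}")


def reaction_rate(rt: ArrayLike, rd: ArrayLike, f: ArrayLike,
                  p: ModelParams) -> ArrayLike:
    """Net activation rate of RT: autocatalytic activation of RD minus
    constitutive and F-actin-dependent inactivation of RT."""
    _check_nonneg(rt=rt, rd=rd, f=f)
    rt = np.asarray(rt, dtype=float)
    activation = (p.k0 + p.alpha * p.k1 * rt**3 / (1.0 + p.k2 * rt**2)) * rd
    inactivation = (p.k3 + p.k4 * (1.0 + p.beta) * f) * rt
    out = activation - inactivation
    return float(out) if out.ndim == 0 else out


def actin_rate(rt: ArrayLike, f: ArrayLike, w: ArrayLike,
               p: ModelParams) -> ArrayLike:
    """Net F-actin assembly rate; ``w`` multiplies the disassembly term."""
    _check_nonneg(rt=rt, f=f)
    rt = np.asarray(rt, dtype=float)
    out = p.k7 + p.k8 * rt**2 / (1.0 + p.k9 * rt**2) - p.k10 * np.asarray(w) * f
    return float(out) if out.ndim == 0 else out


def _laplacian(field: np.ndarray, dx: float) -> np.ndarray:
    # 5-point periodic stencil (delegated here to keep rhs_* self-contained)
    from .simulator import laplacian
    return laplacian(field, dx)


def rhs_reduced(state: State, W: Union[float, np.ndarray], p: ModelParams,
                dx: Optional[float] = None) -> State:
    """Time derivative of the reduced model.

    ``W`` is the noise field multiplying F disassembly (use 1 for the
    deterministic kinetics).  Diffusion is included only when ``dx`` is
    given; with ``dx=None`` (or all-zero diffusivities) the derivative
    is the pointwise reaction part.
    """
    if isinstance(W, np.ndarray) and W.shape != state.shape:
        raise ValueError(f"noise field shape {W.shape} != state shape {state.shape}")
    R = reaction_rate(state.RT, state.RD, state.F, p)
    dRT = np.asarray(R, dtype=float).copy()
    dRD = p.k5 - p.k6 * state.RD - R
    dF = np.asarray(actin_rate(state.RT, state.F, W, p), dtype=float).copy()
    if dx is not None:
        if p.D_RT:
            dRT += p.D_RT * _laplacian(state.RT, dx)
        if p.D_RD:
            dRD += p.D_RD * _laplacian(state.RD, dx)
        if p.D_F:
            dF += p.D_F * _laplacian(state.F, dx)
    return State(np.atleast_2d(dRT), np.atleast_2d(dRD), np.atleast_2d(dF))


def rhs_full(state: FullState, W: Union[float, np.ndarray],
             p: FullModelParams, dx: Optional[float] = None) -> FullState:
    """Time derivative of the full model with membrane/cytoplasm exchange.

    The exchange terms conserve ``RT + RD + RDc/eta`` exactly (no Rho
    production or degradation); F-actin is driven as in the reduced model.
    """
    if p.eta == 0:
        raise ValueError("eta=0 makes RDc non-dynamic; use rhs_reduced "
                         "with k5 = k5_star*RD0 instead")
    R = reaction_rate(state.RT, state.RD, state.F, p)
    dRT = np.asarray(R, dtype=float).copy()
    dRD = p.k5_star * state.RDc - p.k6 * state.RD - R
    dRDc = p.eta * (p.k6 * state.RD - p.k5_star * state.RDc)
    dF = np.asarray(actin_rate(state.RT, state.F, W, p), dtype=float).copy()
    if dx is not None:
        if p.D_RT:
            dRT += p.D_RT * _laplacian(state.RT, dx)
        if p.D_RD:
            dRD += p.D_RD * _laplacian(state.RD, dx)
        if p.D_RDc:
            dRDc = dRDc + p.D_RDc * _laplacian(state.RDc, dx)
        if p.D_F:
            dF += p.D_F * _laplacian(state.F, dx)
    return FullState(np.atleast_2d(dRT), np.atleast_2d(dRD),
                     np.atleast_2d(dF), np.atleast_2d(dRDc))


def _f_of_rt(rt: float, p: ModelParams) -> float:
    # F nullcline: k7 + k8 rt^2/(1+k9 rt^2) = k10 F  (W = 1)
    return (p.k7 + p.k8 * rt**2 / (1.0 + p.k9 * rt**2)) / p.k10


def _rd_of_rt(rt: float, p: ModelParams) -> float:
    # RD nullcline combined with the RT equation: at a uniform fixed point
    # R = 0, hence k5 - k6 RD = 0.
    return p.k5 / p.k6


def _rt_residual(rt: float, p: ModelParams) -> float:
    rd = _rd_of_rt(rt, p)
    f = _f_of_rt(rt, p)
    return reaction_rate(rt, rd, f, p)


def _relax_from_low(p: ModelParams, t_end: float = 5000.0) -> np.ndarray:
    y0 = [1e-3, 1e-3, 1e-3]

    def odes(_t, y):
        rt, rd, f = np.maximum(y, 0.0)
        r = reaction_rate(rt, rd, f, p)
        return [r, p.k5 - p.k6 * rd - r, actin_rate(rt, f, 1.0, p)]

    sol = solve_ivp(odes, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    return sol.y[:, -1]


def uniform_steady_state(p: ModelParams, return_all: bool = False):
    """Uniform fixed point(s) of the deterministic (W=1) kinetics.

    At any uniform fixed point R = 0 forces ``RD = k5/k6`` and the F
    nullcline gives F in closed form, so the problem reduces to a 1D
    root scan in RT.  Multiple non-negative roots may coexist; the one
    reached by relaxation from small positive concentrations is returned
    (or flagged as canonical with ``return_all=True``).
    """
    if p.k10 == 0:
        raise ValueError("k10=0: F has no steady state")
    if p.k6 == 0:
        raise ValueError("k6=0: RD has no steady state")

    # Log-spaced scan with sign-change bracketing, then polish.
    grid = np.concatenate([[0.0], np.geomspace(1e-9, 1e4, 2000)])
    rd = p.k5 / p.k6
    f = (p.k7 + p.k8 * grid**2 / (1.0 + p.k9 * grid**2)) / p.k10
    vals = np.asarray(reaction_rate(grid, rd, f, p))
    roots: List[float] = []
    if abs(vals[0]) < 1e-14:
        roots.append(0.0)
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 and grid[i] > 0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_rt_residual, grid[i], grid[i + 1],
                                args=(p,), xtol=1e-14, rtol=1e-15))
    if not roots:
        raise RuntimeError(
            "no non-negative uniform steady state found; residual range "
            f"[{vals.min():.3g}, {vals.max():.3g}] over RT in [0, 1e4]")

    # Deduplicate near-identical roots.
    uniq: List[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-10 * max(1.0, abs(r)):
            uniq.append(r)

    states = []
    for rt in uniq:
        rd, f = _rd_of_rt(rt, p), _f_of_rt(rt, p)
        res = max(abs(reaction_rate(rt, rd, f, p)),
                  abs(p.k5 - p.k6 * rd),
                  abs(actin_rate(rt, f, 1.0, p)))
        states.append(SteadyState(rt, rd, f, res))

    if len(states) == 1:
        canonical = states[0]
    else:
        target = _relax_from_low(p)
        canonical = min(states, key=lambda s: abs(s.RT_ss - target[0]))
    return (canonical, states) if return_all else canonical


def reduce_full_params(p: FullModelParams) -> ModelParams:
    """Map full-model parameters to the reduced model (k5 = k5_star*RD0)."""
    fields = {f.name: getattr(p, f.name)
              for f in dataclasses.fields(ModelParams)}
    fields["k5"] = p.k5_star * p.RD0
    return ModelParams(**fields)
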