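"""Linear stability of the uniform steady state.

Eigenvalues of ``J - q^2 diag(D)`` over a wavenumber grid classify the
deterministic dynamics into four regimes along the GAP level beta:

* ``higher_uniform`` — stable, high active-Rho fixed point (zone 1)
* ``wave_instability`` — stable at q=0, oscillatory unstable at finite q
* ``oscillatory`` — Hopf-unstable already at q=0
* ``lower_uniform`` — stable, low active-Rho fixed point (zone 2)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .model import SteadyState, uniform_steady_state
from .params import ModelParams

__all__ = [
    "DispersionResult",
    "RegimeDiagram",
    "REGIMES",
    "jacobian",
    "dispersion",
    "classify_regime",
    "beta_scan",
    "default_q_grid",
]

REGIMES = ("higher_uniform", "wave_instability", "oscillatory", "lower_uniform")


@dataclass
class DispersionResult:
    """Growth-rate spectra lambda(q) with the selected mode."""

    q: np.ndarray
    eigenvalues: np.ndarray  # (len(q), 3) complex, sorted by Re descending
    q_star: Optional[float]
    regime: Optional[str] = None

    @property
    def max_growth(self) -> float:
        return float(self.eigenvalues[:, 0].real.max())

    def growth_at(self, q: float) -> complex:
        i = int(np.argmin(np.abs(self.q - q)))
        return complex(self.eigenvalues[i, 0])


@dataclass
class RegimeDiagram:
    """Regime labels over a beta scan with refined boundaries."""

    beta_grid: np.ndarray
    labels: List[str]
    boundaries: List[float] = field(default_factory=list)
    max_re_lambda: Optional[np.ndarray] = None
    q_star: Optional[List[Optional[float]]] = None


def jacobian(p: ModelParams, ss: SteadyState) -> np.ndarray:
    """Analytic Jacobian of the reaction-only kinetics at a fixed point."""
    if ss.residual > 1e-8:
        raise ValueError(f"input is not a fixed point (residual {ss.residual:.3g})")
    rt, rd, f = ss.RT_ss, ss.RD_ss, ss.F_ss
    sat = 1.0 + p.k2 * rt**2
    # d/dRT of k1*RT^3/(1+k2 RT^2) = k1*RT^2*(3 + k2 RT^2)/(1+k2 RT^2)^2
    dact = p.alpha * p.k1 * rt**2 * (3.0 + p.k2 * rt**2) / sat**2
    a_rt = dact * rd - (p.k3 + p.k4 * (1.0 + p.beta) * f)
    a_rd = p.k0 + p.alpha * p.k1 * rt**3 / sat
    a_f = -p.k4 * (1.0 + p.beta) * rt
    satf = 1.0 + p.k9 * rt**2
    # d/dRT of k8*RT^2/(1+k9 RT^2) = 2 k8 RT/(1+k9 RT^2)^2
    g_rt = 2.0 * p.k8 * rt / satf**2
    return np.array([
        [a_rt, a_rd, a_f],
        [-a_rt, -p.k6 - a_rd, -a_f],
        [g_rt, 0.0, -p.k10],
    ])


def default_q_grid(L: float = 256.0, dx: float = 1.0, n: int = 200) -> np.ndarray:
    """q=0 plus ``n`` log-spaced wavenumbers from the domain mode to Nyquist."""
    qs = np.geomspace(2 * np.pi / L, 2 * np.pi / (2 * dx), n)
    return np.concatenate([[0.0], qs])


def dispersion(p: ModelParams, qs: Sequence[float],
               ss: Optional[SteadyState] = None) -> DispersionResult:
    """Eigenvalues of ``J - q^2 diag(D_RT, D_RD, D_F)`` for each q."""
    qs = np.asarray(qs, dtype=float)
    if qs.size == 0:
        raise ValueError("empty wavenumber list")
    if np.any(qs < 0):
        raise ValueError("wavenumbers must be >= 0")
    if ss is None:
        ss = uniform_steady_state(p)
    J = jacobian(p, ss)
    D = np.diag([p.D_RT, p.D_RD, p.D_F])
    eigs = np.empty((qs.size, 3), dtype=complex)
    for i, q in enumerate(qs):
        lam = np.linalg.eigvals(J - q**2 * D)
        eigs[i] = lam[np.argsort(-lam.real)]
    lead = eigs[:, 0].real
    q_star = None
    imax = int(np.argmax(lead))
    if lead[imax] > 0:
        q_star = float(qs[imax])
    return DispersionResult(qs, eigs, q_star)


_STAB_TOL = 1e-9


def classify_regime(p: ModelParams, qs: Optional[Sequence[float]] = None,
                    ss: Optional[SteadyState] = None) -> str:
    """Label the regime of the uniform steady state (see module docstring).

    higher/lower uniform are disambiguated by comparing the stable
    fixed-point RT with the mid-scan fixed point at the geometric centre
    of the unstable window; when no unstable window exists for this
    parameter family the split falls back to the basal balance
    ``RT_ss vs k0*k5/(k3*k6)`` scale.
    """
    disp = dispersion_with_default(p, qs, ss)
    lead0 = disp.eigenvalues[0, 0]  # q=0 row (grid always contains q=0)
    unstable_q0 = lead0.real > _STAB_TOL
    finite = disp.eigenvalues[1:, 0]
    unstable_qpos = bool(np.any(finite.real > _STAB_TOL))
    if unstable_q0:
        return "oscillatory"
    if unstable_qpos:
        i = 1 + int(np.argmax(finite.real))
        if abs(disp.eigenvalues[i, 0].imag) > _STAB_TOL:
            return "wave_instability"
        return "wave_instability"  # stationary Turing would land here too
    # Stable: decide higher vs lower by RT level.
    if ss is None:
        ss = uniform_steady_state(p)
    return "higher_uniform" if _is_high_branch(p, ss) else "lower_uniform"


def dispersion_with_default(p: ModelParams, qs=None, ss=None) -> DispersionResult:
    if qs is None:
        qs = default_q_grid()
    qs = np.asarray(qs, dtype=float)
    if qs[0] != 0.0:
        qs = np.concatenate([[0.0], qs])
    return dispersion(p, qs, ss=ss)


def _is_high_branch(p: ModelParams, ss: SteadyState) -> bool:
    # High branch = autocatalysis dominates basal activation at the
    # fixed point; threshold where the positive feedback term equals
    # the basal term is RT where alpha*k1*RT^3/(1+k2 RT^2) = k0.
    rt = ss.RT_ss
    fb = p.alpha * p.k1 * rt**3 / (1.0 + p.k2 * rt**2)
    return fb > p.k0


def beta_scan(p: ModelParams, betas: Sequence[float],
              qs: Optional[Sequence[float]] = None,
              refine_rel: float = 1e-3) -> RegimeDiagram:
    """Classify regimes over a strictly increasing beta grid and refine
    the regime boundaries by bisection."""
    betas = np.asarray(betas, dtype=float)
    if betas.size > 1 and np.any(np.diff(betas) <= 0):
        raise ValueError("beta grid must be strictly increasing")
    labels, max_re, q_stars = [], [], []
    for b in betas:
        pb = p.replace(beta=b)
        disp = dispersion_with_default(pb, qs)
        labels.append(classify_regime(pb, qs))
        max_re.append(disp.max_growth)
        q_stars.append(disp.q_star)
    boundaries = []
    for i in range(len(betas) - 1):
        if labels[i] != labels[i + 1]:
            lo, hi = betas[i], betas[i + 1]
            lab_lo = labels[i]
            while (hi - lo) > refine_rel * max(abs(hi), 1.0):
                mid = 0.5 * (lo + hi)
                if classify_regime(p.replace(beta=mid), qs) == lab_lo:
                    lo = mid
                else:
                    hi = mid
            boundaries.append(0.5 * (lo + hi))
    return RegimeDiagram(betas, labels, boundaries,
                         np.asarray(max_re), q_stars)
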