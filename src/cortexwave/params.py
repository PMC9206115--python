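"""Model parameter containers and YAML/JSON (de)serialization.

Rate constants follow the circuit's naming: ``k0``–``k10`` for the
reaction kinetics, ``alpha``/``beta`` for the nondimensional GEF/GAP
levels, ``D_*`` for diffusivities (µm²/s) and ``sigma``/``s``/``f``
for the correlated noise that perturbs F-actin disassembly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ModelParams",
    "FullModelParams",
    "DEFAULT_PARAMS",
    "load_params",
    "save_params",
]


# Calibrated defaults (no in-text numeric table exists for this circuit;
# values are scaled so that, at alpha=1, sweeping beta crosses
# higher-uniform -> wave instability -> oscillatory -> lower-uniform with
# wave periods of tens of seconds and wavelengths of tens of µm,
# matching the imaging scale of the frog cortex).
_DEFAULTS = dict(
    k0=0.1,
    k1=30.0,
    k2=10.0,
    k3=0.2,
    k4=1.0,
    k5=0.2,
    k6=0.2,
    k7=0.01,
    k8=0.3,
    k9=0.5,
    k10=0.1,
    alpha=1.0,
    beta=1.5,
    D_RT=2.0,
    D_RD=10.0,
    D_F=0.2,
    sigma=0.15,
    s=2.0,
    f=10.0,
)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the reduced three-field model (membrane pools only).

    Attributes
    ----------
    k0
        Basal Rho activation rate (1/s).
    k1, k2
        Autocatalytic activation coefficient and its saturation constant.
    k3
        Constitutive Rho inactivation rate (1/s).
    k4
        F-actin-dependent Rho inactivation coefficient.
    k5
        Net delivery rate of inactive Rho to the membrane (conc/s).
    k6
        Membrane Rho removal rate (1/s).
    k7, k8, k9
        Basal and Rho-stimulated F-actin assembly rates and saturation.
    k10
        F-actin disassembly rate (1/s).
    alpha, beta
        Nondimensional GEF (Ect2) and GAP (RGA-3/4) levels.
    D_RT, D_RD, D_F
        Diffusivities of active Rho, inactive membrane Rho and F-actin
        (µm²/s).  Active Rho diffuses no faster than inactive Rho.
    sigma, s, f
        Noise standard deviation (mean-1 field), spatial correlation
        length (µm) and regeneration interval (s).
    """

    k0: float = _DEFAULTS["k0"]
    k1: float = _DEFAULTS["k1"]
    k2: float = _DEFAULTS["k2"]
    k3: float = _DEFAULTS["k3"]
    k4: float = _DEFAULTS["k4"]
    k5: float = _DEFAULTS["k5"]
    k6: float = _DEFAULTS["k6"]
    k7: float = _DEFAULTS["k7"]
    k8: float = _DEFAULTS["k8"]
    k9: float = _DEFAULTS["k9"]
    k10: float = _DEFAULTS["k10"]
    alpha: float = _DEFAULTS["alpha"]
    beta: float = _DEFAULTS["beta"]
    D_RT: float = _DEFAULTS["D_RT"]
    D_RD: float = _DEFAULTS["D_RD"]
    D_F: float = _DEFAULTS["D_F"]
    sigma: float = _DEFAULTS["sigma"]
    s: float = _DEFAULTS["s"]
    f: float = _DEFAULTS["f"]

    def __post_init__(self) -> None:
        rates = {n: getattr(self, n) for n in
                 ("k0", "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8",
                  "k9", "k10", "alpha", "beta", "D_RT", "D_RD", "D_F",
                  "sigma")}
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.D_RT > self.D_RD:
            raise ValueError(
                f"active-Rho diffusivity D_RT={self.D_RT} must not exceed "
                f"inactive-Rho diffusivity D_RD={self.D_RD}")
        if self.s <= 0:
            raise ValueError(f"noise correlation length s must be > 0, got {self.s}")
        if self.f <= 0:
            raise ValueError(f"noise regeneration interval f must be > 0, got {self.f}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FullModelParams(ModelParams):
    """Parameters of the full model including the cytoplasmic Rho pool.

    ``eta`` is the membrane/cytoplasm volume ratio; the reduced model is
    the eta -> 0 limit with ``k5 = k5_star * RD0``.
    """

    k5_star: float = 0.2
    RD0: float = 1.0
    eta: float = 5e-5  # frog-oocyte estimate; a default constant, not derived
    D_RDc: float = 10.0

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("k5_star", "RD0", "eta", "D_RDc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.k5 - self.k5_star * self.RD0) > 1e-9 * max(1.0, self.k5):
            raise ValueError(
                f"inconsistent reduced delivery rate: k5={self.k5} but "
                f"k5_star*RD0={self.k5_star * self.RD0}")


DEFAULT_PARAMS = ModelParams()

_REDUCED_KEYS = set(_DEFAULTS)
_FULL_KEYS = _REDUCED_KEYS | {"k5_star", "RD0", "eta", "D_RDc"}


def load_params(path: Union[str, Path]) -> ModelParams:
    """Load a parameter set from a YAML or JSON file.

    The file must contain only recognized keys; the presence of any of
    ``k5_star``, ``RD0``, ``eta``, ``D_RDc`` selects the full model.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    unknown = set(data) - _FULL_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown parameter keys {sorted(unknown)}; "
            f"allowed keys are {sorted(_FULL_KEYS)}")
    cls = FullModelParams if set(data) & {"k5_star", "RD0", "eta", "D_RDc"} else ModelParams
    return cls(**{k: float(v) for k, v in data.items()})


def save_params(p: ModelParams, path: Union[str, Path]) -> None:
    """Write a parameter set as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = p.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
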