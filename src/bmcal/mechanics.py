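"""Bimorph bending: temperature field -> curvature -> deflection profile.

A two-layer beam heated by ``dT`` above its zero-deflection temperature
develops a uniform-through-thickness thermal curvature.  In the subscript
convention 1 = top (structural) layer, 2 = bottom (coating) layer,

    kappa = 6 (alpha1 - alpha2) (t1 + t2) / (t2^2 K) * dT,
    K = 4 + 6 m + 4 m^2 + n m^3 + 1/(n m),   m = t1/t2, n = E1/E2.

This is algebraically identical to the classical bimetal-strip curvature
(Timoshenko 1925), implemented separately in :func:`timoshenko_curvature`
as an independent cross-check.  Deflection follows from integrating
``z'' = kappa(x)`` twice with a clamped anchor (``z(0) = z'(0) = 0``).

Sign convention: reported deflections are positive toward the top layer,
i.e. a beam whose bottom layer expands more (Al under Si3N4) deflects
positively on heating.  Small-deflection (linear) kinematics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import BeamModel, DomainError, LayerStack
from .thermal import ThermalTrace

__all__ = [
    "DeflectionProfile",
    "DeflectionTrace",
    "curvature_coefficient_K",
    "curvature_from_dT",
    "timoshenko_curvature",
    "integrate_deflection",
    "deflection_trace",
]

SIGN_CONVENTION = "positive z toward the top (structural) layer"


@dataclass(frozen=True)
class DeflectionProfile:
    """Deflection shape ``z(x)`` of a clamped-free beam.

    ``x = 0`` is the anchor; ``z(0) = z'(0) = 0`` by construction.
    """

    x: np.ndarray
    z: np.ndarray
    sign_convention: str = SIGN_CONVENTION

    @property
    def tip_deflection(self) -> float:
        return float(self.z[-1])


@dataclass
class DeflectionTrace:
    """Tip-displacement time series — the instrument's observable."""

    times: np.ndarray
    tip: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.tip.shape != self.times.shape:
            raise DomainError("tip/time length mismatch")
        if not np.all(np.isfinite(self.tip)):
            raise DomainError("tip displacements must be finite")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.times,
                             "tip_deflection_m": self.tip})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DeflectionTrace":
        import pandas as pd
        df = pd.read_csv(path, float_precision="round_trip")
        cols = list(df.columns[:2])
        return cls(times=df[cols[0]].to_numpy(),
                   tip=df[cols[1]].to_numpy(), meta={"source": str(path)})


def curvature_coefficient_K(stack: LayerStack) -> float:
    """Dimensionless stiffness factor ``K(m, n)`` of the bimorph curvature.

    ``K = 4 + 6m + 4m^2 + n m^3 + 1/(n m)`` with ``m = t1/t2`` and
    ``n = E1/E2``; equals 16 for identical layers.
    """
    m = stack.t1 / stack.t2
    n = stack.top.youngs_modulus / stack.bottom.youngs_modulus
    return 4.0 + 6.0 * m + 4.0 * m ** 2 + n * m ** 3 + 1.0 / (n * m)


def curvature_from_dT(stack: LayerStack, dT) -> np.ndarray | float:
    """Thermal curvature, positive toward the top layer (vectorised in dT).

    Evaluates ``6 (alpha2 - alpha1)(t1 + t2) / (t2^2 K) * dT``: with the
    higher-expansion layer on the bottom, heating produces positive
    curvature under the package sign convention.
    """
    K = curvature_coefficient_K(stack)
    dalpha = stack.bottom.thermal_expansion - stack.top.thermal_expansion
    coeff = 6.0 * dalpha * (stack.t1 + stack.t2) / (stack.t2 ** 2 * K)
    return coeff * np.asarray(dT, dtype=float) if np.ndim(dT) else coeff * dT


def timoshenko_curvature(stack: LayerStack, dT) -> np.ndarray | float:
    """Classical bimetal-strip curvature (independent oracle).

    ``kappa = 6 (alpha2 - alpha1) dT (1 + m)^2 / (t_tot [3(1+m)^2 +
    (1+mn)(m^2 + 1/(mn))])`` with ``m = t1/t2``, ``n = E1/E2``.  Same sign
    convention as :func:`curvature_from_dT`; for identical layers it
    reduces to ``(3/2) dalpha dT / t_tot``.
    """
    m = stack.t1 / stack.t2
    n = stack.top.youngs_modulus / stack.bottom.youngs_modulus
    dalpha = stack.bottom.thermal_expansion - stack.top.thermal_expansion
    t_tot = stack.t1 + stack.t2
    denom = 3.0 * (1.0 + m) ** 2 + (1.0 + m * n) * (m ** 2 + 1.0 / (m * n))
    coeff = 6.0 * dalpha * (1.0 + m) ** 2 / (t_tot * denom)
    return coeff * np.asarray(dT, dtype=float) if np.ndim(dT) else coeff * dT


def integrate_deflection(x_grid, curvature) -> DeflectionProfile:
    """Integrate ``z'' = kappa(x)`` twice with clamped-anchor conditions.

    Trapezoidal double integration; exact for curvature fields that are at
    most linear in ``x`` on the given grid.
    """
    x = np.asarray(x_grid, dtype=float)
    kappa = np.asarray(curvature, dtype=float)
    if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
        raise DomainError("x grid must be strictly increasing")
    if kappa.shape != x.shape:
        raise DomainError("curvature/grid length mismatch")
    slope = cumulative_trapezoid(kappa, x, initial=0.0)
    z = cumulative_trapezoid(slope, x, initial=0.0)
    return DeflectionProfile(x=x, z=z)


def deflection_trace(thermal: ThermalTrace, model: BeamModel
                     ) -> DeflectionTrace:
    """Tip displacement history implied by a thermal trace.

    The tip displacement is an exact linear map of the temperature rise:
    for a lumped trace the closed form ``tip = kappa(dT) L^2 / 2`` is used;
    for a distributed trace the curvature field is integrated per time
    point.
    """
    L = model.geometry.length
    stack = model.geometry.stack
    T_ref = model.environment.T_ambient
    if thermal.is_distributed:
        x = np.asarray(thermal.x, dtype=float)
        tips = np.empty(thermal.times.size)
        for i in range(thermal.times.size):
            kappa = curvature_from_dT(stack, thermal.temperature[i] - T_ref)
            tips[i] = integrate_deflection(x, kappa).tip_deflection
    else:
        dT = thermal.temperature - T_ref
        tips = curvature_from_dT(stack, dT) * L ** 2 / 2.0
    return DeflectionTrace(times=thermal.times.copy(), tip=tips,
                           meta=dict(thermal.meta,
                                     sign_convention=SIGN_CONVENTION,
                                     model_tag=thermal.model_tag))
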