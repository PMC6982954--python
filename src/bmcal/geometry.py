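"""Beam, layer, sample and environment descriptions.

All quantities are SI.  The central object is :class:`BeamModel`, which
bundles a two-layer cantilever geometry with its environment, the absorbed
optical flux and (optionally) a sample resting on the beam.  The helper
functions compute the dimensionless and geometric quantities that justify
and parameterise the lumped-capacitance thermal treatment: the Biot number,
the characteristic heat-transfer length ``L_c = V / A``, the areal heat
capacity of the layer stack, and the beam-to-sample volume ratio.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple
import warnings

__all__ = [
    "Material",
    "LayerStack",
    "BeamGeometry",
    "SampleSpec",
    "Environment",
    "Irradiation",
    "BeamModel",
    "BiotResult",
    "characteristic_length",
    "biot_number",
    "areal_heat_capacity",
    "volume_ratio",
    "SI3N4",
    "ALUMINUM",
    "YEAST",
]

STEFAN_BOLTZMANN = 5.670374419e-8  # W/(m^2 K^4)

#: Biot number below which a body is treated as isothermal (classical
#: lumped-capacitance criterion).
DEFAULT_BIOT_THRESHOLD = 0.1


class DomainError(ValueError):
    """A physically inadmissible input (non-positive length, etc.)."""


@dataclass(frozen=True)
class Material:
    """Thermophysical and elastic constants of a homogeneous substance.

    Parameters
    ----------
    density : float
        Mass density ``rho`` in kg/m^3.
    specific_heat : float
        Specific heat capacity ``Cp`` at constant pressure in J/(kg K).
    thermal_conductivity : float
        ``k`` in W/(m K).
    thermal_expansion : float
        Linear thermal-expansion coefficient ``alpha`` in 1/K.  May be any
        real number; it is positive for the materials used here.
    youngs_modulus : float
        Elastic modulus ``E`` in Pa.
    """

    name: str
    density: float
    specific_heat: float
    thermal_conductivity: float
    thermal_expansion: float
    youngs_modulus: float

    def __post_init__(self) -> None:
        for attr in ("density", "specific_heat", "thermal_conductivity",
                     "youngs_modulus"):
            if not getattr(self, attr) > 0:
                raise DomainError(f"{self.name}: {attr} must be > 0")

    @property
    def volumetric_heat_capacity(self) -> float:
        """``rho * Cp`` in J/(m^3 K)."""
        return self.density * self.specific_heat


# Default material table.  The layer constants are standard handbook values
# for LPCVD silicon nitride and thin-film aluminium; every entry can be
# overridden in a config.  The yeast entry pairs the literature specific
# heat of 2.17 kJ/(kg K) with a typical wet-cell density of 1100 kg/m^3 and
# the low effective conductivity (0.03 W/m K) used in the Biot estimate for
# a cell-sized object.  Elastic constants of the sample are never used.
SI3N4 = Material("Si3N4", density=3100.0, specific_heat=700.0,
                 thermal_conductivity=20.0, thermal_expansion=2.3e-6,
                 youngs_modulus=250e9)
ALUMINUM = Material("Al", density=2700.0, specific_heat=900.0,
                    thermal_conductivity=237.0, thermal_expansion=23.1e-6,
                    youngs_modulus=70e9)
YEAST = Material("yeast", density=1100.0, specific_heat=2170.0,
                 thermal_conductivity=0.03, thermal_expansion=1e-6,
                 youngs_modulus=1e6)

MATERIALS = {m.name: m for m in (SI3N4, ALUMINUM, YEAST)}


@dataclass(frozen=True)
class LayerStack:
    """Two bonded layers: a structural top layer over a metal coating.

    ``top``/``t1`` is the structural layer (Si3N4 by default), ``bottom``/
    ``t2`` the coating (Al).  Subscript 1 = top, 2 = bottom throughout the
    mechanics.
    """

    top: Material
    bottom: Material
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise DomainError("layer thicknesses must be > 0")

    @property
    def total_thickness(self) -> float:
        return self.t1 + self.t2

    @property
    def conductance_thickness(self) -> float:
        """Axial conduction coefficient ``sum_i k_i t_i`` in W/K."""
        return (self.top.thermal_conductivity * self.t1
                + self.bottom.thermal_conductivity * self.t2)


def areal_heat_capacity(stack: LayerStack) -> float:
    """Heat capacity per unit footprint area, ``sum_i rho_i Cp_i t_i``.

    Units J/(m^2 K).  Additive over layers and independent of their order.
    """
    return (stack.top.volumetric_heat_capacity * stack.t1
            + stack.bottom.volumetric_heat_capacity * stack.t2)


@dataclass(frozen=True)
class BeamGeometry:
    """Rectangular cantilever planform with its layer stack.

    ``characteristic_length_override`` replaces the geometric ``V/A`` in the
    lumped thermal treatment when set (the bundled reference profile pins it
    to 1.0 um even though the two-layer stack is 1.5 um thick).
    """

    length: float
    width: float
    stack: LayerStack
    characteristic_length_override: float | None = None

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise DomainError("beam length and width must be > 0")
        if self.length < 10 * self.stack.total_thickness:
            warnings.warn("beam length is not large compared with its "
                          "thickness; slender-beam assumptions are dubious",
                          stacklevel=2)

    @property
    def footprint_area(self) -> float:
        return self.length * self.width

    @property
    def volume(self) -> float:
        return self.footprint_area * self.stack.total_thickness

    @property
    def characteristic_length(self) -> float:
        """``V / A`` with a single-face heat-transfer area, unless overridden."""
        if self.characteristic_length_override is not None:
            return self.characteristic_length_override
        return characteristic_length(self.volume, self.footprint_area)


@dataclass(frozen=True)
class SampleSpec:
    """A box-shaped sample (e.g. a single yeast cell) resting on the beam.

    ``position_on_beam`` is the centre coordinate of the sample along the
    beam axis, measured from the anchor.  ``volume_override`` and
    ``characteristic_length_override`` replace the geometric values in the
    lumped treatment when set.
    """

    material: Material
    length: float
    height: float
    width: float
    position_on_beam: float
    volume_override: float | None = None
    characteristic_length_override: float | None = None

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.height > 0 and self.width > 0):
            raise DomainError("sample dimensions must be > 0")
        if self.position_on_beam < 0:
            raise DomainError("sample position must be >= 0")

    @property
    def footprint_area(self) -> float:
        return self.length * self.width

    @property
    def volume(self) -> float:
        if self.volume_override is not None:
            return self.volume_override
        return self.footprint_area * self.height

    @property
    def characteristic_length(self) -> float:
        if self.characteristic_length_override is not None:
            return self.characteristic_length_override
        return characteristic_length(self.volume, self.footprint_area)


@dataclass(frozen=True)
class Environment:
    """Ambient conditions and the convective/radiative loss model.

    ``convection_sides`` is ``"both"`` (losses from top and bottom faces,
    effective coefficient ``2 h``) or ``"one"``.  Radiation, when enabled,
    is linearised about the ambient temperature.
    """

    T_ambient: float = 293.15
    h_conv: float = 20.0
    convection_sides: str = "both"
    include_radiation: bool = False
    emissivity: float = 0.0

    def __post_init__(self) -> None:
        if self.h_conv < 0:
            raise DomainError("h_conv must be >= 0")
        if self.T_ambient <= 0:
            raise DomainError("T_ambient must be > 0 (kelvin)")
        if self.convection_sides not in ("one", "both"):
            raise DomainError("convection_sides must be 'one' or 'both'")
        if not 0.0 <= self.emissivity <= 1.0:
            raise DomainError("emissivity must be in [0, 1]")

    @property
    def sides_factor(self) -> int:
        return 2 if self.convection_sides == "both" else 1

    @property
    def h_eff(self) -> float:
        """Effective loss coefficient per unit footprint area, W/(m^2 K).

        Convection from one or both faces plus, optionally, radiation
        linearised as ``4 eps sigma T_amb^3`` per participating face.
        """
        h = self.h_conv * self.sides_factor
        if self.include_radiation:
            h += (4.0 * self.emissivity * STEFAN_BOLTZMANN
                  * self.T_ambient ** 3 * self.sides_factor)
        return h


@dataclass(frozen=True)
class Irradiation:
    """Uniform absorbed optical flux, stepped on at ``t_on`` for ``duration``.

    ``absorbed_flux`` is the flux actually absorbed by the top surface
    (W/m^2); the optics that produce it are outside the model.
    ``wavelength`` is metadata only.
    """

    absorbed_flux: float = 500.0
    t_on: float = 0.0
    duration: float = math.inf
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.absorbed_flux < 0:
            raise DomainError("absorbed_flux must be >= 0")
        if not self.duration > 0:
            raise DomainError("duration must be > 0")

    def flux_at(self, t):
        """Absorbed flux at time(s) ``t`` (vectorised)."""
        import numpy as np
        t = np.asarray(t, dtype=float)
        on = (t >= self.t_on) & (t < self.t_on + self.duration)
        return np.where(on, self.absorbed_flux, 0.0)


class BiotResult(NamedTuple):
    value: float
    lumped_valid: bool


def characteristic_length(volume: float, heat_transfer_area: float) -> float:
    """``L_c = V / A``: volume over heat-transfer area, in metres.

    For a thin plate losing heat through one face this is the thickness.
    """
    if not volume > 0:
        raise DomainError("volume must be > 0")
    if not heat_transfer_area > 0:
        raise DomainError("heat_transfer_area must be > 0")
    return volume / heat_transfer_area


def biot_number(h: float, D: float, k_s: float,
                threshold: float = DEFAULT_BIOT_THRESHOLD) -> BiotResult:
    """Biot number ``Bi = h D / k_s`` with a lumped-validity verdict.

    ``Bi`` is the ratio of internal conductive to external convective
    resistance for a body of size ``D``; ``Bi`` well below 1 means the
    internal temperature gradient is negligible and the body may be treated
    as a lumped mass at a single temperature.
    """
    if not k_s > 0:
        raise DomainError("k_s must be > 0")
    if not D > 0:
        raise DomainError("D must be > 0")
    if h < 0:
        raise DomainError("h must be >= 0")
    bi = h * D / k_s
    return BiotResult(bi, bi < threshold)


@dataclass(frozen=True)
class BeamModel:
    """Full forward-model configuration: beam + environment (+ sample).

    ``volume_convention`` selects how the beam-to-sample volume ratio
    ``V_B / V_S`` is computed:

    ``"3d_boxes"``
        Ratio of the box volumes (default).
    ``"2d_extruded"``
        Ratio of the axial cross-sections, i.e. both bodies share the beam
        width.
    ``"override"``
        Use ``volume_ratio_override`` verbatim (the bundled reference
        profile pins 34, which is not derivable from the box dimensions).
    """

    geometry: BeamGeometry
    environment: Environment = field(default_factory=Environment)
    irradiation: Irradiation = field(default_factory=Irradiation)
    sample: SampleSpec | None = None
    volume_convention: str = "3d_boxes"
    volume_ratio_override: float | None = None

    def __post_init__(self) -> None:
        if self.volume_convention not in ("3d_boxes", "2d_extruded",
                                          "override"):
            raise DomainError("unknown volume convention "
                              f"{self.volume_convention!r}")
        if self.volume_convention == "override" and \
                self.volume_ratio_override is None:
            raise DomainError("volume_convention='override' requires "
                              "volume_ratio_override")
        if self.sample is not None and \
                self.sample.position_on_beam > self.geometry.length:
            raise DomainError("sample position exceeds beam length")

    # -- lumped-model scalars -------------------------------------------
    @property
    def h_eff(self) -> float:
        return self.environment.h_eff

    @property
    def areal_heat_capacity(self) -> float:
        return areal_heat_capacity(self.geometry.stack)

    @property
    def lc_beam(self) -> float:
        return self.geometry.characteristic_length

    @property
    def beam_rho_cp_eff(self) -> float:
        """Effective volumetric heat capacity of the beam as one lump.

        Defined so that ``(rho Cp)_B * L_c,B`` equals the stack's areal
        heat capacity, keeping ``tau_B = (rho Cp)_B L_c,B / h_eff``
        consistent with the two-layer stack whatever ``L_c,B`` is set to.
        """
        return self.areal_heat_capacity / self.lc_beam

    @property
    def lc_sample(self) -> float:
        if self.sample is None:
            raise DomainError("model has no sample")
        return self.sample.characteristic_length

    def volume_ratio(self) -> float:
        """Beam-to-sample volume ratio ``V_B / V_S`` per the convention."""
        if self.sample is None:
            raise DomainError("model has no sample")
        if self.volume_convention == "override":
            return float(self.volume_ratio_override)
        if self.volume_convention == "2d_extruded":
            vb = self.geometry.length * self.geometry.stack.total_thickness
            vs = self.sample.length * self.sample.height
        else:
            vb = self.geometry.volume
            vs = self.sample.volume
        if not vs > 0:
            raise DomainError("sample volume must be > 0")
        return vb / vs

    def mixture_rho_cp(self) -> float:
        """Volume-weighted mean volumetric heat capacity of beam + sample."""
        from . import inversion
        r = self.volume_ratio()
        return inversion.mixture_rho_cp(
            self.beam_rho_cp_eff,
            self.sample.material.volumetric_heat_capacity, r, 1.0)

    def biot_sample(self) -> BiotResult:
        """Biot number of the sample using its longest printed dimension."""
        if self.sample is None:
            raise DomainError("model has no sample")
        d = max(self.sample.length, self.sample.height, self.sample.width)
        return biot_number(self.environment.h_conv, d,
                           self.sample.material.thermal_conductivity)

    def without_sample(self) -> "BeamModel":
        """The same configuration with the sample removed (calibration run)."""
        return BeamModel(geometry=self.geometry,
                         environment=self.environment,
                         irradiation=self.irradiation,
                         sample=None,
                         volume_convention="3d_boxes",
                         volume_ratio_override=None)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration (provenance)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def volume_ratio(beam: BeamModel | BeamGeometry,
                 sample: SampleSpec | None = None, **kw) -> float:
    """``V_B / V_S`` for a configured model, or for a geometry/sample pair."""
    if isinstance(beam, BeamModel):
        return beam.volume_ratio()
    model = BeamModel(geometry=beam, sample=sample, **kw)
    return model.volume_ratio()
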