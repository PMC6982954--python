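"""Configuration files and bundled profiles.

Configs are TOML (or JSON) documents with sections mirroring the domain
types, all in SI units::

    [beam]            # length, width, optional characteristic_length
    [layers.top]      # material name or inline constants + thickness
    [layers.bottom]
    [sample]          # optional: material, length, height, width, position
    [environment]     # T_ambient, h_conv, convection_sides, radiation
    [irradiation]     # absorbed_flux, t_on, duration
    [inversion]       # volume_convention, volume_ratio

:func:`reference_profile` returns the bundled scenario: a 600 x 76 um
Si3N4 beam (1 um) with a 500 nm Al underside, 500 W/m^2 absorbed flux,
h = 20 W/(m^2 K), and a 5 x 2 x 5 um yeast-like sample at mid-beam.  Its
lumped characteristic lengths (1.0 um beam, 1.1 um sample) and the volume
ratio 34 are pinned constants of the scenario rather than quantities
derived from the box dimensions; see docs/methods.md for why.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from .geometry import (BeamGeometry, BeamModel, Environment, Irradiation,
                       LayerStack, Material, SampleSpec, MATERIALS,
                       SI3N4, ALUMINUM, YEAST, DomainError)

__all__ = ["reference_profile", "default_profile", "load_config",
           "model_from_dict"]

UM = 1e-6


def reference_profile(convection_sides: str = "both",
                      with_sample: bool = True) -> BeamModel:
    """The bundled reference scenario (see module docstring).

    ``convection_sides`` defaults to ``"both"`` (losses from top and
    bottom faces); pass ``"one"`` for top-face-only convection.
    """
    stack = LayerStack(top=SI3N4, bottom=ALUMINUM, t1=1.0e-6, t2=0.5e-6)
    geom = BeamGeometry(length=600e-6, width=76e-6, stack=stack,
                        characteristic_length_override=1.0e-6)
    sample = SampleSpec(material=YEAST, length=5e-6, height=2e-6,
                        width=5e-6, position_on_beam=300e-6,
                        characteristic_length_override=1.1e-6) \
        if with_sample else None
    return BeamModel(
        geometry=geom,
        environment=Environment(T_ambient=293.15, h_conv=20.0,
                                convection_sides=convection_sides),
        irradiation=Irradiation(absorbed_flux=500.0, t_on=0.0,
                                wavelength=635e-9),
        sample=sample,
        volume_convention="override" if with_sample else "3d_boxes",
        volume_ratio_override=34.0 if with_sample else None)


def default_profile(with_sample: bool = True) -> BeamModel:
    """Same hardware, but every geometric quantity derived from the boxes.

    Characteristic lengths are ``V/A`` (1.5 um beam, 2.0 um sample) and the
    volume ratio is the ratio of box volumes — the self-consistent
    convention used by the synthetic recovery experiments when no printed
    constant has to be honoured.
    """
    m = reference_profile(with_sample=with_sample)
    geom = BeamGeometry(length=m.geometry.length, width=m.geometry.width,
                        stack=m.geometry.stack)
    sample = None
    if with_sample:
        s = m.sample
        sample = SampleSpec(material=s.material, length=s.length,
                            height=s.height, width=s.width,
                            position_on_beam=s.position_on_beam)
    return BeamModel(geometry=geom, environment=m.environment,
                     irradiation=m.irradiation, sample=sample,
                     volume_convention="3d_boxes")


PROFILES = {"reference": reference_profile, "default": default_profile}


def _material_from(entry: dict | str) -> Material:
    if isinstance(entry, str):
        try:
            return MATERIALS[entry]
        except KeyError:
            raise DomainError(f"unknown material {entry!r}; known: "
                              f"{sorted(MATERIALS)}") from None
    base = dict(entry)
    name = base.pop("name", "custom")
    if "material" in base:  # named base with overrides
        ref = MATERIALS[base.pop("material")]
        fields = {
            "density": ref.density,
            "specific_heat": ref.specific_heat,
            "thermal_conductivity": ref.thermal_conductivity,
            "thermal_expansion": ref.thermal_expansion,
            "youngs_modulus": ref.youngs_modulus,
        }
        name = ref.name
    else:
        fields = {}
    fields.update(base)
    return Material(name=name, **fields)


def model_from_dict(doc: dict) -> BeamModel:
    """Build a :class:`BeamModel` from a parsed config document."""
    layers = doc.get("layers", {})
    top = layers.get("top", {})
    bottom = layers.get("bottom", {})
    stack = LayerStack(
        top=_material_from(top.get("material", "Si3N4")),
        bottom=_material_from(bottom.get("material", "Al")),
        t1=float(top.get("thickness", 1.0 * UM)),
        t2=float(bottom.get("thickness", 0.5 * UM)))
    beam = doc.get("beam", {})
    geom = BeamGeometry(
        length=float(beam.get("length", 600 * UM)),
        width=float(beam.get("width", 76 * UM)),
        stack=stack,
        characteristic_length_override=(
            float(beam["characteristic_length"])
            if "characteristic_length" in beam else None))
    sample = None
    if "sample" in doc:
        s = doc["sample"]
        sample = SampleSpec(
            material=_material_from(s.get("material", "yeast")),
            length=float(s.get("length", 5 * UM)),
            height=float(s.get("height", 2 * UM)),
            width=float(s.get("width", 5 * UM)),
            position_on_beam=float(s.get("position_on_beam",
                                         geom.length / 2)),
            volume_override=(float(s["volume"]) if "volume" in s else None),
            characteristic_length_override=(
                float(s["characteristic_length"])
                if "characteristic_length" in s else None))
    env = doc.get("environment", {})
    irr = doc.get("irradiation", {})
    inv = doc.get("inversion", {})
    return BeamModel(
        geometry=geom,
        environment=Environment(
            T_ambient=float(env.get("T_ambient", 293.15)),
            h_conv=float(env.get("h_conv", 20.0)),
            convection_sides=env.get("convection_sides", "both"),
            include_radiation=bool(env.get("include_radiation", False)),
            emissivity=float(env.get("emissivity", 0.0))),
        irradiation=Irradiation(
            absorbed_flux=float(irr.get("absorbed_flux", 500.0)),
            t_on=float(irr.get("t_on", 0.0)),
            duration=float(irr.get("duration", float("inf"))),
            wavelength=(float(irr["wavelength"])
                        if "wavelength" in irr else None)),
        sample=sample,
        volume_convention=inv.get("volume_convention",
                                  "override" if "volume_ratio" in inv
                                  else "3d_boxes"),
        volume_ratio_override=(float(inv["volume_ratio"])
                               if "volume_ratio" in inv else None))


def load_config(path: str | Path) -> BeamModel:
    """Load a TOML or JSON config file into a :class:`BeamModel`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    return model_from_dict(doc)
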