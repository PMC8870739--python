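"""Materials: elemental mixtures with density, and their attenuation.

A :class:`Material` is a named elemental mixture (mass fractions summing to
one) with a bulk density.  Mass attenuation coefficients follow the mixture
rule -- the mass-fraction-weighted sum of the elemental coefficients -- and
linear coefficients are expressed per millimetre, the natural unit of the
voxel geometries used here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .xsdata import CrossSectionSet, default_cross_sections

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class Material:
    """Named elemental mixture with density [g/cm^3].

    ``glandular_share`` is the glandular mass fraction of the material
    (1 for glandular tissue, 0.5 for the 50/50 breast-CT mixture, ...),
    used by glandular dosimetry on homogeneous-mixture phantoms.
    """

    name: str
    mass_fractions: dict[str, float]
    density: float
    glandular_share: float = 0.0

    def __post_init__(self):
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, not 1")
        if not self.density > 0:
            raise ValueError(f"density of {self.name!r} must be positive")

    def __hash__(self):
        return hash((self.name, self.density))


def mix_materials(components: list[tuple[Material, float]],
                  name: str) -> Material:
    """Homogeneous mixture of materials by mass weight.

    Mass fractions mix linearly; density assumes volume additivity,
    1/rho = sum(w_i / rho_i).
    """
    weights = np.array([w for _, w in components], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=_FRACTION_TOL):
        raise ValueError("component weights must sum to 1")
    fractions: dict[str, float] = {}
    for mat, w in components:
        for el, f in mat.mass_fractions.items():
            fractions[el] = fractions.get(el, 0.0) + w * f
    density = 1.0 / sum(w / m.density for m, w in components)
    share = sum(w * m.glandular_share for m, w in components)
    return Material(name, fractions, density, glandular_share=share)


@lru_cache(maxsize=1)
def material_library(path=None) -> dict[str, Material]:
    """Load the bundled material library (or a YAML file of the same form)."""
    if path is None:
        src = resources.files("voxray") / "data" / "materials.yaml"
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        name: Material(name, entry["mass_fractions"], entry["density"],
                       glandular_share=entry.get("glandular_share", 0.0))
        for name, entry in raw.items()
    }


def get_material(name: str) -> Material:
    return material_library()[name]


def mass_attenuation(material: Material, energy_kev, process: str = "total",
                     xs: CrossSectionSet | None = None):
    """Mass attenuation coefficient of ``material`` [cm^2/g].

    Mixture rule: the mass-fraction-weighted sum of the elemental tables;
    ``total`` is the sum of photoelectric, coherent and incoherent parts.
    """
    xs = xs or default_cross_sections()
    e = np.asarray(energy_kev, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for el, w in material.mass_fractions.items():
        out = out + w * xs.element_mu(el, e, process)
    return out if out.shape else float(out)


def linear_attenuation(material: Material, energy_kev,
                       process: str = "total",
                       xs: CrossSectionSet | None = None):
    """Linear attenuation coefficient [1/mm] (mu/rho * rho, cm -> mm)."""
    return mass_attenuation(material, energy_kev, process, xs) \
        * material.density / 10.0
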