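"""Shared fixtures: small geometries, narrow beams, and a photoelectric-only
cross-section set for transport oracle tests."""
from __future__ import annotations

import shutil
from pathlib import Path

import numpy as np
import pytest

from voxray import (CTSetup, DetectorFrame, PlanarSetup, Spectrum,
                    get_material)
from voxray.materials import Material
from voxray.phantoms import LABEL_MIXTURE, LabelVolume
from voxray.xsdata import CrossSectionSet


@pytest.fixture(scope="session")
def coarse_planar():
    """Planar geometry with a coarse detector (fast scoring)."""
    return PlanarSetup(det_nx=95, det_ny=95)


@pytest.fixture(scope="session")
def narrow_frame():
    """Tiny detector rectangle under the source: a pencil-beam collimator."""
    return DetectorFrame(np.array([0.0, 0.0, 660.0]),
                         np.array([1.0, 0.0, 0.0]),
                         np.array([0.0, 1.0, 0.0]),
                         width=0.5, height=0.5, nx=1, ny=1)


@pytest.fixture(scope="session")
def mono50():
    return Spectrum(np.array([50.0]), np.array([1.0]))


def water_slab(thickness_mm: float = 20.0, z0: float = 300.0,
               half_width: float = 100.0) -> LabelVolume:
    """Water slab perpendicular to the planar beam axis."""
    n = int(2 * half_width)
    nz = int(thickness_mm)
    labels = np.full((n, n, nz), LABEL_MIXTURE, dtype=np.uint8)
    return LabelVolume((1.0, 1.0, 1.0), (-half_width, -half_width, z0),
                       labels, {0: get_material("air"),
                                LABEL_MIXTURE: get_material("water")})


@pytest.fixture(scope="session")
def absorber_xs(tmp_path_factory) -> CrossSectionSet:
    """Cross sections where element H is a pure photoelectric absorber
    (coherent and incoherent tables zeroed)."""
    from importlib import resources
    src = resources.files("voxray") / "data"
    d = Path(tmp_path_factory.mktemp("xs"))
    shutil.copytree(str(src / "cross_sections"), d / "cross_sections")
    for f in ("muen_air.csv", "muen_al.csv", "form_factors.json"):
        shutil.copy(str(src / f), d / f)
    arr = np.loadtxt(d / "cross_sections" / "H.csv")
    tot = arr[:, 1] + arr[:, 2] + arr[:, 3]
    tiny = np.full_like(tot, 1e-30)
    np.savetxt(d / "cross_sections" / "H.csv",
               np.column_stack([arr[:, 0], tot, tiny, tiny]),
               header="absorber-H: photoelectric only", fmt="%.6e")
    return CrossSectionSet(d)


def absorber(density: float, name: str = "absorber") -> Material:
    """Pure-H material used with ``absorber_xs`` as an ideal absorber."""
    return Material(name, {"H": 1.0}, density)
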