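"""Acquisition geometries: planar (mammography-like) and rotating CT.

World frames
------------
* Planar: the source sits at the origin, the beam axis is +z, and the
  detector plane is at z = SDD.  The source's perpendicular foot on the
  detector lies at the *top edge midpoint* (half-field irradiation), with
  u along the detector width (x) and v down the detector height (y).
* CT: the rotation axis is the vertical z axis through the isocenter
  (origin).  At projection angle phi the source is at
  (SOD cos phi, SOD sin phi, 0) and the detector top-edge midpoint at
  -(SDD - SOD) along the same ray, with v pointing downwards (-z): a
  half-cone beam with the focal spot aligned to the detector's upper side.
  The phantom stays fixed; source and detector rotate.

All distances are mm, angles degrees.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DetectorFrame:
    """Rectangular detector: top-edge midpoint, in-plane axes, pixel grid."""

    top_center: np.ndarray     # world position of the top edge midpoint
    u: np.ndarray              # unit vector along the width
    v: np.ndarray              # unit vector down the height
    width: float
    height: float
    nx: int
    ny: int

    def __post_init__(self):
        for name in ("top_center", "u", "v"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (np.isclose(np.linalg.norm(self.u), 1)
                and np.isclose(np.linalg.norm(self.v), 1)):
            raise ValueError("u and v must be unit vectors")
        if self.width <= 0 or self.height <= 0 or self.nx <= 0 or self.ny <= 0:
            raise ValueError("degenerate detector")

    @property
    def pitch(self) -> tuple[float, float]:
        return self.width / self.nx, self.height / self.ny

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    def corners(self) -> np.ndarray:
        c = self.top_center
        w2 = self.width / 2.0
        return np.array([c - w2 * self.u,
                         c + w2 * self.u,
                         c - w2 * self.u + self.height * self.v,
                         c + w2 * self.u + self.height * self.v])


@dataclass(frozen=True)
class PlanarSetup:
    """Planar half-field geometry (flat-field / compressed-breast studies)."""

    sdd: float = 660.0
    sod: float = 595.0
    airgap: float = 15.0
    det_width: float = 285.0
    det_height: float = 285.0
    det_nx: int = 1900
    det_ny: int = 1900

    def __post_init__(self):
        if not self.sod < self.sdd:
            raise ValueError("SOD must be smaller than SDD")
        if min(self.det_width, self.det_height) <= 0 \
                or min(self.det_nx, self.det_ny) <= 0:
            raise ValueError("degenerate detector")

    @property
    def source(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def detector(self) -> DetectorFrame:
        return DetectorFrame(np.array([0.0, 0.0, self.sdd]),
                             np.array([1.0, 0.0, 0.0]),
                             np.array([0.0, 1.0, 0.0]),
                             self.det_width, self.det_height,
                             self.det_nx, self.det_ny)


@dataclass(frozen=True)
class CTSetup:
    """Rotating half-cone breast-CT geometry."""

    sod_isocenter: float = 650.0
    sdd: float = 923.0
    det_width: float = 290.0
    det_height: float = 230.0
    det_pitch: float = 0.25
    n_projections: int = 360

    def __post_init__(self):
        if not self.sod_isocenter < self.sdd:
            raise ValueError("SOD must be smaller than SDD")

    @property
    def angular_step(self) -> float:
        return 360.0 / self.n_projections

    @property
    def det_nx(self) -> int:
        return int(round(self.det_width / self.det_pitch))

    @property
    def det_ny(self) -> int:
        return int(round(self.det_height / self.det_pitch))

    def view(self, projection_index: int) -> tuple[np.ndarray, DetectorFrame]:
        """Source position and detector frame of one projection."""
        if not 0 <= projection_index < self.n_projections:
            raise IndexError("projection index out of range")
        phi = np.deg2rad(projection_index * self.angular_step)
        c, s = np.cos(phi), np.sin(phi)
        source = np.array([self.sod_isocenter * c,
                           self.sod_isocenter * s, 0.0])
        odd = self.sdd - self.sod_isocenter
        top_center = np.array([-odd * c, -odd * s, 0.0])
        u = np.array([-s, c, 0.0])
        v = np.array([0.0, 0.0, -1.0])
        frame = DetectorFrame(top_center, u, v, self.det_width,
                              self.det_height, self.det_nx, self.det_ny)
        return source, frame


def rotate_projection(setup: CTSetup, projection_index: int):
    """Functional alias of :meth:`CTSetup.view`."""
    return setup.view(projection_index)


# -- ray/detector intersections ------------------------------------------------

def intersect_detector(origins: np.ndarray, directions: np.ndarray,
                       frame: DetectorFrame):
    """Parameter t and in-plane (du, dv) of ray/detector-plane intersections.

    Rays parallel to the plane or moving away get t = +inf.
    """
    n = frame.normal
    denom = directions @ n
    num = (frame.top_center - origins) @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(denom) > 1e-12, num / denom, np.inf)
    t = np.where(t > 0, t, np.inf)
    t_fin = np.where(np.isfinite(t), t, 0.0)
    d = origins + directions * t_fin[..., None] - frame.top_center
    du = np.where(np.isfinite(t), d @ frame.u, np.inf)
    dv = np.where(np.isfinite(t), d @ frame.v, np.inf)
    return t, du, dv


def detector_pixel(position, frame: DetectorFrame, tol: float = 1e-6):
    """Pixel index (i, j) of a world position on the detector, or None.

    ``position`` must lie on the detector plane within ``tol``; indices are
    0-based with half-open pixel bins.
    """
    d = np.asarray(position, dtype=float) - frame.top_center
    if abs(float(d @ frame.normal)) > tol:
        raise ValueError("position is not on the detector plane")
    du = float(d @ frame.u) + frame.width / 2.0
    dv = float(d @ frame.v)
    px, py = frame.pitch
    if not (0 <= du < frame.width and 0 <= dv < frame.height):
        return None
    return int(du // px), int(dv // py)


# -- collimated source sampling ------------------------------------------------

def _orthonormal_basis(axis: np.ndarray):
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2, a


def sample_collimated_directions(source: np.ndarray, frame: DetectorFrame,
                                 n: int, rng: np.random.Generator,
                                 return_stats: bool = False):
    """``n`` unit directions uniform over the detector's solid angle.

    Sampling is by rejection from the bounding cone of the detector
    rectangle: directions are drawn uniformly in the spherical cap and kept
    if the ray intersects the rectangle, which yields exactly
    uniform-in-solid-angle, unweighted (analog) beam directions.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    center = frame.top_center + (frame.height / 2.0) * frame.v
    axis = center - np.asarray(source, dtype=float)
    e1, e2, a = _orthonormal_basis(axis)
    corners = frame.corners() - source
    cos_max = min(
        float(c @ a / np.linalg.norm(c)) for c in corners)
    out = np.empty((n, 3))
    got = 0
    proposed = 0
    while got < n:
        m = max(int(1.3 * (n - got)) + 16, 32)
        proposed += m
        cos_t = 1.0 - rng.random(m) * (1.0 - cos_max)
        sin_t = np.sqrt(1.0 - cos_t ** 2)
        phi = rng.random(m) * 2.0 * np.pi
        dirs = (sin_t * np.cos(phi))[:, None] * e1 \
            + (sin_t * np.sin(phi))[:, None] * e2 \
            + cos_t[:, None] * a
        t, du, dv = intersect_detector(
            np.broadcast_to(source, (m, 3)), dirs, frame)
        ok = (np.abs(du) <= frame.width / 2.0) & (dv >= 0.0) \
            & (dv <= frame.height) & np.isfinite(t)
        take = min(int(ok.sum()), n - got)
        out[got:got + take] = dirs[ok][:take]
        got += take
    if return_stats:
        cone_sr = 2.0 * np.pi * (1.0 - cos_max)
        return out, {"proposed": proposed, "accepted": n,
                     "cone_solid_angle_sr": cone_sr}
    return out


def rectangle_solid_angle(source: np.ndarray, frame: DetectorFrame,
                          n_grid: int = 600) -> float:
    """Solid angle [sr] of the detector rectangle, by numeric integration
    of dA cos(theta) / r^2 over the rectangle."""
    w2 = frame.width / 2.0
    us = (np.arange(n_grid) + 0.5) / n_grid * frame.width - w2
    vs = (np.arange(n_grid) + 0.5) / n_grid * frame.height
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    pts = (frame.top_center[None, None, :]
           + uu[..., None] * frame.u + vv[..., None] * frame.v)
    d = pts - np.asarray(source, dtype=float)
    r = np.linalg.norm(d, axis=-1)
    cos = np.abs(d @ frame.normal) / r
    dA = (frame.width / n_grid) * (frame.height / n_grid)
    return float(np.sum(cos / r ** 2) * dA)


def analytic_flat_field(source: np.ndarray, frame: DetectorFrame
                        ) -> np.ndarray:
    """Relative expected flat-field map: per-pixel solid angle (A cos/r^2),
    normalized to its maximum."""
    px, py = frame.pitch
    us = (np.arange(frame.nx) + 0.5) * px - frame.width / 2.0
    vs = (np.arange(frame.ny) + 0.5) * py
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    pts = (frame.top_center[None, None, :]
           + uu[..., None] * frame.u + vv[..., None] * frame.v)
    d = pts - np.asarray(source, dtype=float)
    r = np.linalg.norm(d, axis=-1)
    cos = np.abs(d @ frame.normal) / r
    omega = cos / r ** 2
    return omega / omega.max()
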