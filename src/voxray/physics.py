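"""Photon interaction physics: Compton and Rayleigh angular sampling.

Compton scattering uses the free-electron Klein-Nishina cross section,
sampled with Kahn's composition-rejection method; the electron is not
tracked, so the energy transfer E - E' is deposited at the interaction
site by the transport engine.  Rayleigh (coherent) scattering samples the
Thomson cross section modulated by the material's atomic form factors
(independent-atom mixture), using the analytically invertible one-term
screened form-factor model shipped with the cross-section tables.
"""
from __future__ import annotations

import numpy as np

from .constants import HC_KEV_ANGSTROM, MEC2_KEV, R_E_CM
from .materials import Material
from .xsdata import CrossSectionSet, default_cross_sections


# -- Klein-Nishina (incoherent / Compton) ---------------------------------------

def compton_scattered_energy(energy_kev, cos_theta):
    """Compton kinematics: scattered photon energy E' [keV]."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    return energy_kev / (1.0 + k * (1.0 - np.asarray(cos_theta)))


def kn_total_cross_section(energy_kev):
    """Total Klein-Nishina cross section per electron [cm^2]."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    t = 1.0 + 2.0 * k
    return 2.0 * np.pi * R_E_CM ** 2 * (
        (1.0 + k) / k ** 2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
        + np.log(t) / (2.0 * k) - (1.0 + 3.0 * k) / t ** 2)


def kn_differential(energy_kev, cos_theta):
    """Klein-Nishina differential cross section dsigma/dOmega [cm^2/sr]."""
    k = energy_kev / MEC2_KEV
    ratio = 1.0 / (1.0 + k * (1.0 - cos_theta))  # E'/E
    return 0.5 * R_E_CM ** 2 * ratio ** 2 \
        * (ratio + 1.0 / ratio - 1.0 + cos_theta ** 2)


def sample_compton(energy_kev: np.ndarray, rng: np.random.Generator):
    """Sample Compton scattering angles with Kahn's method.

    Returns ``(cos_theta, e_scattered)`` arrays matching ``energy_kev``.
    """
    e = np.asarray(energy_kev, dtype=float)
    k = e / MEC2_KEV
    cos_out = np.empty_like(e)
    pending = np.arange(e.size)
    kf = k.ravel()
    while pending.size:
        kk = kf[pending]
        r1 = rng.random(pending.size)
        r2 = rng.random(pending.size)
        r3 = rng.random(pending.size)
        branch1 = r1 <= (1.0 + 2.0 * kk) / (9.0 + 2.0 * kk)
        x = np.where(branch1,
                     1.0 + 2.0 * kk * r2,
                     (1.0 + 2.0 * kk) / (1.0 + 2.0 * kk * r2))
        cos_t = 1.0 - (x - 1.0) / kk
        accept = np.where(
            branch1,
            r3 <= 4.0 * (1.0 / x - 1.0 / x ** 2),
            r3 <= 0.5 * (cos_t ** 2 + 1.0 / x))
        accept &= np.abs(cos_t) <= 1.0
        done = pending[accept]
        cos_out.ravel()[done] = cos_t[accept]
        pending = pending[~accept]
    return cos_out, compton_scattered_energy(e, cos_out)


# -- Rayleigh (coherent) ---------------------------------------------------------

class RayleighSampler:
    """Coherent-scatter angle sampler for one material.

    The one-term screened form factor F(q, Z) = Z/(1+(b q)^2)^2 makes the
    q^2 distribution analytically invertible per element; the element is
    chosen proportionally to its (energy-dependent) integrated coherent
    weight, then the Thomson polar factor (1+cos^2)/2 is applied by
    rejection.  With ``unit_form_factor=True`` the sampler reduces to the
    pure Thomson distribution (used for validation).
    """

    def __init__(self, material: Material,
                 xs: CrossSectionSet | None = None,
                 unit_form_factor: bool = False):
        xs = xs or default_cross_sections()
        self.unit_form_factor = unit_form_factor
        els = sorted(material.mass_fractions)
        self._z = np.array([xs.form_factor_params(el)[0] for el in els],
                           dtype=float)
        a = np.array([xs.form_factor_params(el)[1] for el in els])
        self._b = np.array([xs.form_factor_params(el)[2] for el in els])
        w = np.array([material.mass_fractions[el] for el in els])
        self._n = w / a  # relative number densities

    def sample_cos(self, energy_kev: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        cos_out = np.empty_like(e)
        pending = np.arange(e.size)
        ef = e.ravel()
        while pending.size:
            m = pending.size
            if self.unit_form_factor:
                cos_t = 2.0 * rng.random(m) - 1.0
            else:
                q_max = 4.0 * np.pi * ef[pending] / HC_KEV_ANGSTROM  # 1/A
                vmax = (self._b[None, :] * q_max[:, None]) ** 2  # u_max^2
                gmax = (1.0 - (1.0 + vmax) ** -3) / 3.0
                wsel = (self._n * self._z ** 2 / self._b ** 2)[None, :] * gmax
                cdf = np.cumsum(wsel, axis=1)
                pick = (rng.random(m)[:, None] * cdf[:, -1:] > cdf).sum(axis=1)
                rows = np.arange(m)
                g = gmax[rows, pick]
                v = (1.0 - 3.0 * rng.random(m) * g) ** (-1.0 / 3.0) - 1.0
                frac = v / vmax[rows, pick]  # (q/q_max)^2 = sin^2(theta/2)
                cos_t = 1.0 - 2.0 * frac
            accept = rng.random(m) <= 0.5 * (1.0 + cos_t ** 2)
            done = pending[accept]
            cos_out.ravel()[done] = cos_t[accept]
            pending = pending[~accept]
        return cos_out


def sample_thomson(n: int, rng: np.random.Generator) -> np.ndarray:
    """Polar-angle cosines from the pure Thomson distribution (for tests)."""
    out = np.empty(n)
    got = 0
    while got < n:
        m = n - got
        cos_t = 2.0 * rng.random(m) - 1.0
        keep = rng.random(m) <= 0.5 * (1.0 + cos_t ** 2)
        k = int(keep.sum())
        out[got:got + k] = cos_t[keep]
        got += k
    return out


# -- direction rotation ----------------------------------------------------------

def rotate_directions(directions: np.ndarray, cos_theta: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by polar angle (given cosine) and uniform azimuth."""
    d = np.asarray(directions, dtype=float)
    cos_t = np.asarray(cos_theta, dtype=float)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t ** 2))
    phi = 2.0 * np.pi * rng.random(cos_t.shape)
    # orthonormal basis perpendicular to each direction
    helper = np.zeros_like(d)
    small_x = np.abs(d[:, 0]) < 0.9
    helper[small_x, 0] = 1.0
    helper[~small_x, 1] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    out = (cos_t[:, None] * d
           + (sin_t * np.cos(phi))[:, None] * e1
           + (sin_t * np.sin(phi))[:, None] * e2)
    return out / np.linalg.norm(out, axis=1, keepdims=True)
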