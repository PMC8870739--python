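"""X-ray spectra: binned fluence distributions, filtration, HVL, sampling.

A :class:`Spectrum` is a set of energy bins (keV, strictly increasing) with
relative photon-fluence weights.  Beam quality is characterized by the
half-value layer (HVL) in aluminium, defined on air kerma: the Al thickness
that halves sum_i w_i * E_i * (mu_en/rho)_air(E_i) * exp(-mu_Al(E_i) t).

Two fixture spectra are bundled: a 28 kV W-anode / Al-filtered mammography
beam and an 80 kV W-anode / Cu-filtered breast-CT beam whose Cu thickness was
calibrated so that its HVL is 5.74 mm Al (the calibration is recorded in the
fixture header).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .materials import Material, get_material, linear_attenuation
from .xsdata import CrossSectionSet, default_cross_sections

#: names of the bundled fixture spectra
FIXTURES = ("w28kv_al", "w80kv_cu")


@dataclass(frozen=True)
class Spectrum:
    """Binned photon-fluence spectrum (bin energies in keV)."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape or e.size == 0:
            raise ValueError("energies and weights must be equal-length 1D")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin energies must be strictly increasing")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    # -- basic quantities ----------------------------------------------------
    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy [keV]."""
        return float(np.average(self.energies, weights=self.weights))

    def normalized(self) -> "Spectrum":
        return Spectrum(self.energies, self.weights / self.weights.sum())

    # -- I/O -------------------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "Spectrum":
        """Read a two-column text spectrum (energy_keV, relative fluence)."""
        arr = np.loadtxt(path, comments="#", ndmin=2)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def fixture(cls, name: str) -> "Spectrum":
        """Load one of the bundled fixture spectra (see :data:`FIXTURES`)."""
        if name not in FIXTURES:
            raise KeyError(f"unknown fixture {name!r}; have {FIXTURES}")
        path = resources.files("voxray") / "data" / "spectra" / f"{name}.txt"
        with resources.as_file(path) as p:
            return cls.from_file(p)

    def to_file(self, path, header: str = "") -> None:
        np.savetxt(path, np.column_stack([self.energies, self.weights]),
                   header=header + "\nenergy_keV relative_fluence",
                   fmt="%.6e")

    # -- physics ----------------------------------------------------------------
    def filtered(self, material: Material, thickness_mm: float,
                 xs: CrossSectionSet | None = None) -> "Spectrum":
        """Attenuate each bin by exp(-mu(E) * t) (Beer-Lambert filtration)."""
        if thickness_mm < 0:
            raise ValueError("filter thickness must be >= 0")
        mu = linear_attenuation(material, self.energies, xs=xs)  # 1/mm
        return Spectrum(self.energies,
                        self.weights * np.exp(-mu * thickness_mm))

    def sample_energies(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` photon energies from the bin distribution (inverse CDF
        over bins; each draw returns a bin energy)."""
        if n <= 0:
            raise ValueError("n must be positive")
        p = self.weights / self.weights.sum()
        idx = rng.choice(self.energies.size, size=n, p=p)
        return self.energies[idx]


def filter_spectrum(spectrum: Spectrum, material: Material,
                    thickness_mm: float,
                    xs: CrossSectionSet | None = None) -> Spectrum:
    """Functional alias of :meth:`Spectrum.filtered`."""
    return spectrum.filtered(material, thickness_mm, xs)


def air_kerma_per_fluence(spectrum: Spectrum,
                          xs: CrossSectionSet | None = None) -> float:
    """Relative air kerma of the spectrum: sum w * E * (mu_en/rho)_air."""
    xs = xs or default_cross_sections()
    return float(np.sum(spectrum.weights * spectrum.energies
                        * xs.muen("air", spectrum.energies)))


def hvl_al(spectrum: Spectrum, xs: CrossSectionSet | None = None,
           tol_mm: float = 1e-4) -> float:
    """Half-value layer in mm of aluminium, on air kerma.

    Solved by bracketing and bisection to ``tol_mm``.
    """
    xs = xs or default_cross_sections()
    al = get_material("aluminum")
    mu_al = linear_attenuation(al, spectrum.energies, xs=xs)  # 1/mm
    kerma_w = spectrum.weights * spectrum.energies \
        * xs.muen("air", spectrum.energies)
    k0 = kerma_w.sum()
    if k0 <= 0:
        raise ValueError("spectrum has zero air kerma")

    def kerma(t):
        return np.sum(kerma_w * np.exp(-mu_al * t))

    lo, hi = 0.0, 1.0
    while kerma(hi) > 0.5 * k0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - nonphysical input
            raise RuntimeError("HVL bracketing failed")
    while hi - lo > tol_mm:
        mid = 0.5 * (lo + hi)
        if kerma(mid) > 0.5 * k0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
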