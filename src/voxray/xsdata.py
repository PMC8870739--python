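"""Bundled elemental photon cross-section tables and their interpolation.

The package ships mass cross sections (photoelectric, coherent, incoherent;
cm^2/g) for the elements needed by breast-tissue dosimetry (H, C, N, O, P),
air (N, O, Ar, C), the aluminium beam-quality reference and the copper
filter, tabulated on a dense logarithmic grid over 1-200 keV, together with
mass energy-absorption coefficients for air and Al and the screened
form-factor parameters used for coherent-scatter sampling.

Interpolation is linear in log-log space, which is monotone within each
segment and is the standard convention for photon attenuation tables.
"""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Iterable

import numpy as np

from .constants import TABLE_EMAX_KEV, TABLE_EMIN_KEV

PROCESSES = ("photoelectric", "coherent", "incoherent", "total")


class UnknownElementError(KeyError):
    """Requested element has no bundled cross-section table."""


class EnergyRangeError(ValueError):
    """Requested energy lies outside the tabulated 1-200 keV range."""


def _loglog_interp(e, table_e, table_v):
    le = np.log(np.asarray(e, dtype=float))
    return np.exp(np.interp(le, np.log(table_e), np.log(table_v)))


class CrossSectionSet:
    """In-memory view of the bundled elemental tables.

    Parameters
    ----------
    data_dir:
        Optional directory holding ``cross_sections/<El>.csv``,
        ``muen_air.csv``, ``muen_al.csv`` and ``form_factors.json``.
        Defaults to the tables bundled with the package.
    """

    def __init__(self, data_dir=None):
        if data_dir is None:
            data_dir = resources.files("voxray") / "data"
        self._dir = data_dir
        self._tables: dict[str, np.ndarray] = {}
        with (data_dir / "form_factors.json").open() as fh:
            self._ff = json.load(fh)
        self._muen = {}
        for medium in ("air", "al"):
            arr = np.loadtxt(str(data_dir / f"muen_{medium}.csv"))
            self._muen[medium] = (arr[:, 0], arr[:, 1])

    # -- elemental cross sections -------------------------------------------
    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._ff["elements"])

    def _table(self, symbol: str) -> np.ndarray:
        if symbol not in self._tables:
            if symbol not in self._ff["elements"]:
                raise UnknownElementError(
                    f"no bundled cross sections for element {symbol!r}")
            path = self._dir / "cross_sections" / f"{symbol}.csv"
            arr = np.loadtxt(str(path))
            if np.any(arr < 0):
                raise ValueError(f"negative entries in table {symbol}")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"energy grid not increasing in {symbol}")
            self._tables[symbol] = arr
        return self._tables[symbol]

    def element_mu(self, symbol: str, energy_kev, process: str = "total"):
        """Elemental mass cross section [cm^2/g] at ``energy_kev``.

        ``process`` is one of photoelectric / coherent / incoherent / total.
        """
        if process not in PROCESSES:
            raise ValueError(f"unknown process {process!r}")
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < TABLE_EMIN_KEV) or np.any(e > TABLE_EMAX_KEV):
            raise EnergyRangeError(
                f"energy outside tabulated range "
                f"[{TABLE_EMIN_KEV}, {TABLE_EMAX_KEV}] keV")
        tab = self._table(symbol)
        if process == "total":
            v = tab[:, 1] + tab[:, 2] + tab[:, 3]
        else:
            v = tab[:, 1 + PROCESSES.index(process)]
        out = _loglog_interp(e, tab[:, 0], np.maximum(v, 1e-30))
        return out if out.shape else float(out)

    # -- form factors --------------------------------------------------------
    def form_factor_params(self, symbol: str) -> tuple[int, float, float]:
        """(Z, A, screening length b [Angstrom]) of the coherent-scatter
        form-factor model F(q, Z) = Z / (1 + (b q)^2)^2."""
        try:
            p = self._ff["elements"][symbol]
        except KeyError as exc:
            raise UnknownElementError(symbol) from exc
        return p["Z"], p["A"], p["b_angstrom"]

    # -- energy absorption ----------------------------------------------------
    def muen(self, medium: str, energy_kev):
        """Mass energy-absorption coefficient [cm^2/g] for 'air' or 'al'."""
        e_tab, v_tab = self._muen[medium.lower()]
        e = np.asarray(energy_kev, dtype=float)
        e = np.clip(e, e_tab[0], e_tab[-1])
        out = _loglog_interp(e, e_tab, v_tab)
        return out if out.shape else float(out)


@lru_cache(maxsize=1)
def default_cross_sections() -> CrossSectionSet:
    """The package-bundled :class:`CrossSectionSet` (cached singleton)."""
    return CrossSectionSet()
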