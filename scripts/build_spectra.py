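"""Build the bundled spectrum fixtures.

Both fixtures are produced from a Kramers-type semi-empirical tungsten-anode
model: unfiltered bremsstrahlung photon fluence proportional to
(kVp - E) / E on a 0.5 keV grid, plus (above the K edge) the W K
characteristic lines, then Beer-Lambert filtration through the stated
filters using the bundled attenuation tables.

* ``w28kv_al``  -- 28 kV, 0.5 mm Al filtration (mammography-like beam).
* ``w80kv_cu``  -- 80 kV, 2 mm Al inherent + Cu added filtration; the Cu
  thickness is calibrated by bisection so the air-kerma HVL equals
  5.74 mm Al, and is recorded in the header.

Run from the repository root: ``python scripts/build_spectra.py``.
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from voxray.materials import get_material  # noqa: E402
from voxray.spectra import Spectrum, hvl_al  # noqa: E402

OUT = ROOT / "src" / "voxray" / "data" / "spectra"

# W K-alpha/K-beta lines [keV] and relative intensities
W_K_LINES = [(57.98, 0.57), (59.32, 1.00), (67.24, 0.33), (69.10, 0.09)]
K_LINE_FLUENCE_FRACTION = 0.06  # of total unfiltered fluence, at 80 kV


def kramers(kvp: float, emin: float = 8.0, step: float = 0.5) -> Spectrum:
    e = np.arange(emin, kvp - step / 2, step)
    w = (kvp - e) / e
    return Spectrum(e, w / w.sum())


def with_k_lines(spec: Spectrum, kvp: float) -> Spectrum:
    if kvp <= 69.5:  # below W K edge: no K fluorescence
        return spec
    w = spec.weights.copy()
    rel = np.array([r for _, r in W_K_LINES])
    amp = K_LINE_FLUENCE_FRACTION * w.sum() * rel / rel.sum()
    for (line_e, _), a in zip(W_K_LINES, amp):
        idx = int(np.argmin(np.abs(spec.energies - line_e)))
        w[idx] += a
    return Spectrum(spec.energies, w)


def build_28kv() -> tuple[Spectrum, str]:
    al = get_material("aluminum")
    # 1 mm Al-equivalent inherent (window + anode self-filtration of the
    # bare Kramers shape) + the named 0.5 mm Al added filter
    spec = kramers(28.0).filtered(al, 1.0).filtered(al, 0.5)
    hvl = hvl_al(spec)
    header = ("28 kV W-anode spectrum, Kramers model,\n"
              "1 mm Al-equivalent inherent + 0.5 mm Al added filtration\n"
              f"computed air-kerma HVL = {hvl:.3f} mm Al\n"
              "bin width 0.5 keV")
    return spec.normalized(), header


def build_80kv(target_hvl: float = 5.74) -> tuple[Spectrum, str]:
    al = get_material("aluminum")
    cu = get_material("copper")
    base = with_k_lines(kramers(80.0), 80.0).filtered(al, 2.0)

    lo, hi = 0.0, 2.0
    assert hvl_al(base.filtered(cu, hi)) > target_hvl
    while hi - lo > 1e-5:
        mid = 0.5 * (lo + hi)
        if hvl_al(base.filtered(cu, mid)) < target_hvl:
            lo = mid
        else:
            hi = mid
    t_cu = 0.5 * (lo + hi)
    spec = base.filtered(cu, t_cu)
    hvl = hvl_al(spec)
    header = ("80 kV W-anode spectrum, Kramers model + W K lines,\n"
              f"2 mm Al inherent + {t_cu:.4f} mm Cu added filtration\n"
              f"(Cu thickness calibrated once so the air-kerma HVL is "
              f"{target_hvl} mm Al; computed HVL = {hvl:.4f} mm Al)\n"
              "bin width 0.5 keV")
    return spec.normalized(), header


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec28, hdr28 = build_28kv()
    spec28.to_file(OUT / "w28kv_al.txt", hdr28)
    print(hdr28.replace("\n", " | "))
    print(f"  mean energy {spec28.mean_energy():.2f} keV, "
          f"{spec28.energies.size} bins")
    spec80, hdr80 = build_80kv()
    spec80.to_file(OUT / "w80kv_cu.txt", hdr80)
    print(hdr80.replace("\n", " | "))
    print(f"  mean energy {spec80.mean_energy():.2f} keV, "
          f"{spec80.energies.size} bins")


if __name__ == "__main__":
    main()
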