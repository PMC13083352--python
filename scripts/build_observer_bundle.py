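#!/usr/bin/env python
"""Regenerate the standard-observer bundle from the public CVRL tables.

Downloads the tabulated standard-observer functions from the Colour & Vision
Research Laboratory (http://www.cvrl.org/) — the Stockman–Sharpe 10° cone
fundamentals, the photopic luminous efficiency function, the CIE scotopic
luminous efficiency function V'(λ), the melanopic fundamental, the macular
pigment and lens optical density tables and the CIE 1964 10° colour-matching
functions — resamples them onto the canonical 390–780 nm / 2 nm grid and
writes a bundle directory readable by ``substim.load_observer_bundle``.

Requires network access; the package's tests and demo never need this —
they use the synthetic observer from ``substim.synth``.  Check CVRL's terms
before redistributing the downloaded tables.

Usage::

    python scripts/build_observer_bundle.py --out observer_bundle/
"""

from __future__ import annotations

import argparse
import io
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

from substim import CANONICAL_GRID, Spectrum, resample, write_spectra
from substim.spectra import UNIT_OPTICAL_DENSITY, UNIT_SENSITIVITY, WavelengthGrid

# CVRL CSV downloads (energy units, 1 nm where available).  Columns are
# wavelength followed by the tabulated function(s); missing entries in the
# raw files are blank and read as NaN (treated as zero sensitivity).
SOURCES = {
    # wavelength, L, M, S (linear energy, 10 deg, 1 nm)
    "fundamentals": "http://www.cvrl.org/database/data/cones/linss10e_1.csv",
    # CIE 1951 scotopic V'(lambda)
    "scotopic": "http://www.cvrl.org/database/data/lum/scvle_1.csv",
    # Stockman-Sharpe 10 deg photopic luminous efficiency
    "vlambda": "http://www.cvrl.org/database/data/lum/linCIE2008v10e_1.csv",
    # macular pigment optical density (Stockman, Sharpe & Fach)
    "macular": "http://www.cvrl.org/database/data/maclens/macss_1.csv",
    # lens optical density components
    "lens": "http://www.cvrl.org/database/data/maclens/lenssmj_1.csv",
    # CIE 1964 10 deg colour-matching functions
    "cmfs": "http://www.cvrl.org/database/data/cmfs/ciexyz64_1.csv",
}

# The CIE S 026 melanopic action spectrum is distributed by CIE; supply it
# as a local CSV (wavelength, mel) via --melanopsin.


def fetch(url: str) -> pd.DataFrame:
    with urllib.request.urlopen(url) as response:  # noqa: S310 - fixed URLs
        raw = response.read().decode("utf-8")
    return pd.read_csv(io.StringIO(raw), header=None)


def to_spectrum(wl: np.ndarray, values: np.ndarray, unit: str) -> Spectrum:
    values = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    steps = np.diff(wl)
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    return resample(Spectrum(grid, values, unit), CANONICAL_GRID)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument(
        "--melanopsin",
        type=Path,
        default=None,
        help="Local CSV (wavelength, mel) with the melanopic action spectrum.",
    )
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    funds = fetch(SOURCES["fundamentals"])
    wl = funds.iloc[:, 0].to_numpy(float)
    spectra = {
        name: to_spectrum(wl, funds.iloc[:, i + 1], UNIT_SENSITIVITY)
        for i, name in enumerate(("L", "M", "S"))
    }
    write_spectra(out / "cone_fundamentals.csv", [(n, spectra[n]) for n in ("L", "M", "S")])

    sco = fetch(SOURCES["scotopic"])
    rod = to_spectrum(sco.iloc[:, 0].to_numpy(float), sco.iloc[:, 1], UNIT_SENSITIVITY)
    write_spectra(out / "rod_fundamental.csv", [("rod", rod)])

    vl = fetch(SOURCES["vlambda"])
    vlam = to_spectrum(vl.iloc[:, 0].to_numpy(float), vl.iloc[:, 1], UNIT_SENSITIVITY)
    write_spectra(out / "vlambda.csv", [("V", vlam)])

    mac = fetch(SOURCES["macular"])
    mac_s = to_spectrum(mac.iloc[:, 0].to_numpy(float), mac.iloc[:, 1], UNIT_OPTICAL_DENSITY)
    mac_s = mac_s.with_values(mac_s.values / mac_s.values.max())  # peak OD of 1
    write_spectra(out / "macular_density.csv", [("macular", mac_s)])

    lens = fetch(SOURCES["lens"])
    lens_wl = lens.iloc[:, 0].to_numpy(float)
    tl1 = to_spectrum(lens_wl, lens.iloc[:, 1], UNIT_OPTICAL_DENSITY)
    tl2 = to_spectrum(lens_wl, lens.iloc[:, 2], UNIT_OPTICAL_DENSITY)
    write_spectra(out / "lens_density.csv", [("TL1", tl1), ("TL2", tl2)])

    cmf = fetch(SOURCES["cmfs"])
    cmf_wl = cmf.iloc[:, 0].to_numpy(float)
    bars = [to_spectrum(cmf_wl, cmf.iloc[:, i], UNIT_SENSITIVITY) for i in (1, 2, 3)]
    write_spectra(
        out / "cmfs_1964.csv",
        [("xbar", bars[0]), ("ybar", bars[1]), ("zbar", bars[2])],
    )

    if args.melanopsin is not None:
        mel_table = pd.read_csv(args.melanopsin)
        mel = to_spectrum(
            mel_table.iloc[:, 0].to_numpy(float), mel_table.iloc[:, 1], UNIT_SENSITIVITY
        )
    else:
        raise SystemExit(
            "no --melanopsin table given; the melanopic action spectrum must be "
            "supplied locally (CIE S 026 toolbox export)"
        )
    write_spectra(out / "melanopsin_fundamental.csv", [("mel", mel)])
    print(f"observer bundle written to {out}")


if __name__ == "__main__":
    main()
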