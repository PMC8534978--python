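"""Packaged reference tables.

Two small CSVs ship with oxikin:

* ``species_energies`` — published B3LYP/6-31G(d,p) enthalpies for carnosic
  acid (CA), its two phenoxyl radicals, oleic acid (OA), its two allylic
  radicals, and the hydrogen atom. CA energies are in kJ/mol, OA energies
  in hartree, exactly as tabulated in the literature.
* ``regression_lines`` — the published linearized kinetic fits (slope,
  intercept, R^2 on the 1000/T abscissa) for OA alone and with carnosic
  acid (CA+OA) or tert-butylhydroquinone (TBHQ+OA): Arrhenius and Eyring
  lines from Rancimat data, Flynn-Wall-Ozawa and Kissinger-Akahira-Sunose
  lines from DSC data.

The raw induction-period, DSC and absorbance measurements behind these
lines were never published; :mod:`oxikin.simulate` generates structurally
identical data in their place.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


def path_for(name: str) -> Path:
    """Filesystem path of a packaged CSV (``species_energies`` or
    ``regression_lines``)."""
    ref = resources.files("oxikin").joinpath("data", f"{name}.csv")
    with resources.as_file(ref) as p:
        if not p.exists():
            raise ValueError(f"no packaged dataset named {name!r}")
        return p


def species_energies() -> pd.DataFrame:
    """Published species enthalpies (columns label, energy, unit, role)."""
    from .io import read_table

    return read_table(path_for("species_energies"), "species")


def regression_lines(method: str | None = None) -> pd.DataFrame:
    """Published kinetic regression lines, optionally filtered by method."""
    from .io import read_table

    df = read_table(path_for("regression_lines"), "regression_lines")
    if method is not None:
        df = df[df["method"] == method].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"no lines with method {method!r}")
    return df
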