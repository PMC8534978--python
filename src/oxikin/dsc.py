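"""Isoconversional DSC kinetics: Flynn-Wall-Ozawa and Kissinger-Akahira-Sunose.

Non-isothermal DSC scans at several heating rates beta (K/min) each show an
oxidation exotherm peaking at Tp. At the peak the extent of conversion is
approximately constant across heating rates, so the model-free
linearizations

* FWO:  lg(beta)        = -0.4567 * E/(R Tp) + C1
* KAS:  lg(beta/Tp^2)   = -0.4343 * E/(R Tp) + C2

give the apparent activation energy E from the slope of an OLS fit against
1000/Tp without assuming a reaction model. ``lg`` is log10 throughout: the
KAS constant 0.4343 = 1/ln(10) fixes the convention, and no natural-log
variant is offered (mixing the two silently corrupts E by a factor ln 10).
Only peak-temperature (fixed-conversion) analysis is implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import ABSCISSA, FWO_FACTOR, KAS_FACTOR, R_J_PER_MOL_K

_FACTORS = {"fwo": FWO_FACTOR, "kas": KAS_FACTOR}


@dataclass
class IsoconversionalFit:
    sample: str
    method: str  # "fwo" | "kas"
    slope: float  # per 1000/Tp (K)
    intercept: float  # C1 or C2
    r_squared: float
    ea_kj_mol: float
    n_points: int = 0
    abscissa: str = field(default=ABSCISSA)

    def __post_init__(self) -> None:
        if self.method not in _FACTORS:
            raise ValueError(f"unknown isoconversional method {self.method!r}")
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def slope_to_ea_iso(slope: float, method: str) -> float:
    """Apparent activation energy (kJ/mol) from a lg-vs-1000/Tp slope.

    E = -slope * R / c with c = 0.4567 (FWO) or 0.4343 (KAS).
    """
    try:
        factor = _FACTORS[method]
    except KeyError:
        raise ValueError(f"unknown isoconversional method {method!r}") from None
    return -slope * R_J_PER_MOL_K / factor


def _prepare(peaks: pd.DataFrame, sample: str) -> tuple[np.ndarray, np.ndarray]:
    sub = peaks[peaks["sample"] == sample]
    if sub.empty:
        raise ValueError(f"no rows for sample {sample!r}")
    beta = sub["beta_K_per_min"].to_numpy(dtype=float)
    tp = sub["tp_K"].to_numpy(dtype=float)
    if (beta <= 0).any() or (tp <= 0).any():
        raise ValueError(f"sample {sample!r}: beta and Tp must be positive")
    n_distinct = len(np.unique(beta))
    if n_distinct < 2:
        raise ValueError(
            f"sample {sample!r}: need >=2 distinct heating rates, got {n_distinct}"
        )
    if n_distinct < 3:
        warnings.warn(
            f"sample {sample!r}: only {n_distinct} distinct heating rates",
            stacklevel=3,
        )
    return beta, tp


def _fit(peaks: pd.DataFrame, sample: str, method: str) -> IsoconversionalFit:
    beta, tp = _prepare(peaks, sample)
    x = 1000.0 / tp
    y = np.log10(beta) if method == "fwo" else np.log10(beta / tp**2)
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: zero variance in 1000/Tp")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    return IsoconversionalFit(
        sample=sample,
        method=method,
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rvalue**2),
        ea_kj_mol=slope_to_ea_iso(slope, method),
        n_points=len(beta),
    )


def fwo_fit(peaks: pd.DataFrame, sample: str) -> IsoconversionalFit:
    """Flynn-Wall-Ozawa fit: lg(beta) vs 1000/Tp for one sample."""
    return _fit(peaks, sample, "fwo")


def kas_fit(peaks: pd.DataFrame, sample: str) -> IsoconversionalFit:
    """Kissinger-Akahira-Sunose fit: lg(beta/Tp^2) vs 1000/Tp for one sample."""
    return _fit(peaks, sample, "kas")


def fit_from_line(
    sample: str, method: str, slope: float, intercept: float,
    r_squared: float = float("nan"),
) -> IsoconversionalFit:
    """Rebuild an isoconversional fit from a published (slope, intercept) line."""
    return IsoconversionalFit(
        sample=sample,
        method=method,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        ea_kj_mol=slope_to_ea_iso(slope, method),
    )
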