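"""Rancimat induction-period kinetics: Arrhenius and Eyring (ACT) fits.

The Rancimat accelerated-oxidation test reports an induction period IP(T),
the time until conductivity of trapped volatiles rises sharply. Treating
the onset as first-order-like gives an effective rate constant k = 1/IP
(h^-1). Two linearizations are fitted by ordinary least squares:

* Arrhenius:  ln k      = ln A - Ea/(R T)          -> Ea, ln A
* Eyring/ACT: ln (k/T)  = ln(kB/h) + dS/R - dH/(R T) -> dH, dS

Both use the abscissa x = 1000/T (K), so Ea = -slope * R lands in kJ/mol
directly. ln(kB/h) defaults to the tabulated reproduction value 21.46
(see :mod:`oxikin.constants`); pass ``ln_kb_over_h=LN_KB_OVER_H_SI`` for
SI s^-1 rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    ABSCISSA,
    CELSIUS_OFFSET,
    LN_KB_OVER_H_DEFAULT,
    R_J_PER_MOL_K,
)

logger = logging.getLogger(__name__)


@dataclass
class KineticFit:
    """Result of one linearized kinetic fit.

    Exactly the parameter pair matching ``method`` is populated:
    (ea_kj_mol, ln_a) for ``arrhenius``; (delta_h_kj_mol,
    delta_s_j_mol_k) plus ``ln_kb_over_h`` for ``eyring``.
    """

    sample: str
    method: str  # "arrhenius" | "eyring"
    slope: float  # per 1000/T (K)
    intercept: float
    r_squared: float
    n_points: int = 0
    ea_kj_mol: float | None = None
    ln_a: float | None = None
    delta_h_kj_mol: float | None = None
    delta_s_j_mol_k: float | None = None
    ln_kb_over_h: float | None = None
    abscissa: str = field(default=ABSCISSA)

    def __post_init__(self) -> None:
        if self.method not in ("arrhenius", "eyring"):
            raise ValueError(f"unknown kinetic method {self.method!r}")
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def to_kelvin(temperature: np.ndarray | float, unit: str = "C") -> np.ndarray | float:
    """Convert temperatures to kelvin. ``unit`` must be 'C' or 'K' (explicit;
    values around 100-130 are ambiguous, so there is no autodetection)."""
    if unit == "K":
        return temperature
    if unit == "C":
        return np.asarray(temperature) + CELSIUS_OFFSET if np.ndim(temperature) else temperature + CELSIUS_OFFSET
    raise ValueError(f"temperature unit must be 'C' or 'K', got {unit!r}")


def rate_constants(ip: pd.DataFrame) -> pd.DataFrame:
    """Convert an induction-period table to rate constants k = 1/IP (h^-1).

    ``ip`` needs columns sample, temperature_K, ip_hours. Rows with
    non-positive IP raise a validation error naming the row.
    """
    bad = ip.index[ip["ip_hours"] <= 0].tolist()
    if bad:
        raise ValueError(f"ip_hours must be > 0; offending rows: {bad}")
    out = ip.copy()
    out["k_per_hour"] = 1.0 / out["ip_hours"]
    return out


def _prepare_xy(rates: pd.DataFrame, sample: str) -> tuple[np.ndarray, np.ndarray]:
    sub = rates[rates["sample"] == sample]
    if sub.empty:
        raise ValueError(f"no rows for sample {sample!r}")
    T = sub["temperature_K"].to_numpy(dtype=float)
    k = sub["k_per_hour"].to_numpy(dtype=float)
    n_distinct = len(np.unique(T))
    if n_distinct < 2:
        raise ValueError(
            f"sample {sample!r}: need >=2 distinct temperatures, got {n_distinct}"
        )
    if n_distinct < 3:
        warnings.warn(
            f"sample {sample!r}: only {n_distinct} distinct temperatures; "
            "fits with fewer than 3 are poorly constrained",
            stacklevel=3,
        )
    return T, k


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: zero variance in 1000/T")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def slope_to_ea(slope: float) -> float:
    """Activation energy in kJ/mol from an ln k vs 1000/T slope: -slope * R."""
    return -slope * R_J_PER_MOL_K


def eyring_params(
    slope: float, intercept: float, ln_kb_over_h: float = LN_KB_OVER_H_DEFAULT
) -> tuple[float, float]:
    """(dH kJ/mol, dS J/(mol K)) from an ln(k/T) vs 1000/T line."""
    delta_h = -slope * R_J_PER_MOL_K
    delta_s = (intercept - ln_kb_over_h) * R_J_PER_MOL_K
    return delta_h, delta_s


def arrhenius_fit(rates: pd.DataFrame, sample: str) -> KineticFit:
    """OLS of ln k on 1000/T for one sample; Ea = -slope * R, ln A = intercept."""
    T, k = _prepare_xy(rates, sample)
    x = 1000.0 / T
    slope, intercept, r2 = _ols(x, np.log(k))
    return KineticFit(
        sample=sample,
        method="arrhenius",
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(T),
        ea_kj_mol=slope_to_ea(slope),
        ln_a=intercept,
    )


def eyring_fit(
    rates: pd.DataFrame, sample: str, ln_kb_over_h: float = LN_KB_OVER_H_DEFAULT
) -> KineticFit:
    """OLS of ln(k/T) on 1000/T; dH = -slope * R, dS = (intercept - ln(kB/h)) * R."""
    if ln_kb_over_h == LN_KB_OVER_H_DEFAULT:
        logger.warning(
            "eyring_fit using reproduction constant ln(kB/h)=%.2f; the SI s^-1 "
            "value is 23.76 (oxikin.constants.LN_KB_OVER_H_SI)",
            ln_kb_over_h,
        )
    T, k = _prepare_xy(rates, sample)
    x = 1000.0 / T
    slope, intercept, r2 = _ols(x, np.log(k / T))
    delta_h, delta_s = eyring_params(slope, intercept, ln_kb_over_h)
    return KineticFit(
        sample=sample,
        method="eyring",
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=len(T),
        delta_h_kj_mol=delta_h,
        delta_s_j_mol_k=delta_s,
        ln_kb_over_h=ln_kb_over_h,
    )


def fit_from_line(
    sample: str,
    method: str,
    slope: float,
    intercept: float,
    r_squared: float = float("nan"),
    ln_kb_over_h: float = LN_KB_OVER_H_DEFAULT,
) -> KineticFit:
    """Build a KineticFit from an already-published regression line.

    Used to turn printed (slope, intercept) pairs back into activation
    parameters without the underlying raw data.
    """
    if method == "arrhenius":
        return KineticFit(
            sample=sample, method=method, slope=slope, intercept=intercept,
            r_squared=r_squared, ea_kj_mol=slope_to_ea(slope), ln_a=intercept,
        )
    if method == "eyring":
        dh, ds = eyring_params(slope, intercept, ln_kb_over_h)
        return KineticFit(
            sample=sample, method=method, slope=slope, intercept=intercept,
            r_squared=r_squared, delta_h_kj_mol=dh, delta_s_j_mol_k=ds,
            ln_kb_over_h=ln_kb_over_h,
        )
    raise ValueError(f"unknown kinetic method {method!r}")
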