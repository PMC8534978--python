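"""DPPH/ABTS radical-scavenging rates and IC50 estimation.

Both assays measure the bleaching of a stable chromogenic radical:
SR% = (A0 - A1)/A0 * 100, where A0 is the control absorbance and A1 the
absorbance after reaction with the antioxidant. The assay identity (DPPH
at 517 nm vs ABTS at 734 nm) is metadata only — the arithmetic is
identical. IC50, the concentration at 50% scavenging, is estimated either
by linear interpolation between the bracketing concentrations (default)
or by a four-parameter logistic fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def scavenging_rate(a0: float, a1: float) -> float:
    """SR% = (A0 - A1)/A0 * 100. Negative results (A1 > A0) warn."""
    if a0 <= 0:
        raise ValueError(f"control absorbance A0 must be > 0, got {a0}")
    if a1 < 0:
        raise ValueError(f"sample absorbance A1 must be >= 0, got {a1}")
    sr = (a0 - a1) / a0 * 100.0
    if sr < 0:
        warnings.warn(
            f"negative scavenging rate ({sr:.1f}%): sample absorbance exceeds control",
            stacklevel=2,
        )
    return sr


def add_scavenging_rates(curve: pd.DataFrame) -> pd.DataFrame:
    """Append an ``sr_percent`` column to a (concentration, a0, a1) table."""
    out = curve.copy()
    out["sr_percent"] = [
        scavenging_rate(a0, a1) for a0, a1 in zip(out["a0"], out["a1"])
    ]
    return out


def four_pl(c, bottom, top, ic50, hill):
    """Four-parameter logistic: bottom + (top-bottom) / (1 + (ic50/c)^hill).

    Defined by continuity as ``bottom`` at c = 0.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, ic50 / np.where(c > 0, c, 1.0), np.inf)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


def _ic50_interpolate(conc: np.ndarray, sr: np.ndarray) -> float:
    order = np.argsort(conc, kind="stable")
    conc, sr = conc[order], sr[order]
    if not (np.all(np.diff(sr) >= 0) or np.all(np.diff(sr) <= 0)):
        warnings.warn("dose-response is not monotonic; interpolation uses the "
                      "first 50% bracket in ascending concentration", stacklevel=3)
    exact = np.isclose(sr, 50.0)
    if exact.any():
        return float(conc[exact][0])
    for i in range(len(conc) - 1):
        lo, hi = sr[i], sr[i + 1]
        if (lo - 50.0) * (hi - 50.0) < 0:
            return float(conc[i] + (50.0 - lo) * (conc[i + 1] - conc[i]) / (hi - lo))
    raise ValueError(
        "no pair of consecutive concentrations brackets SR = 50%; widen the "
        "concentration range or use method='four_pl'"
    )


def _ic50_four_pl(conc: np.ndarray, sr: np.ndarray) -> float:
    if sr.max() < 50.0 or sr.min() > 50.0:
        raise ValueError(
            "measured scavenging never crosses 50% "
            f"(range {sr.min():.1f}-{sr.max():.1f}%); IC50 would be pure "
            "extrapolation — widen the concentration range"
        )
    p0 = [
        float(min(sr.min(), 0.0)),
        float(max(sr.max(), 100.0)),
        float(np.median(conc[conc > 0])) if (conc > 0).any() else 1.0,
        1.0,
    ]
    bounds = ([-50.0, 50.0, 1e-9, 0.05], [50.0, 200.0, 1e6, 20.0])
    popt, _ = curve_fit(four_pl, conc, sr, p0=p0, bounds=bounds, maxfev=20000)
    bottom, top, x50, hill = popt
    if not (bottom < 50.0 < top):
        raise ValueError(
            f"fitted curve never crosses 50% (bottom={bottom:.1f}, top={top:.1f})"
        )
    # solve 50 = bottom + (top-bottom)/(1+(x50/c)^hill) for c
    ratio = (top - 50.0) / (50.0 - bottom)
    return float(x50 / ratio ** (1.0 / hill))


def ic50(curve: pd.DataFrame, method: str = "interpolate") -> float:
    """Half-scavenging concentration from a dose-response table.

    ``curve`` needs columns concentration and sr_percent (or a0/a1, from
    which SR is derived). ``method`` is 'interpolate' (linear, between the
    first pair of consecutive concentrations bracketing 50%) or 'four_pl'
    (least-squares 4PL; returns where the fitted curve crosses 50%).
    """
    if "sr_percent" not in curve.columns:
        curve = add_scavenging_rates(curve)
    if len(curve) < 2:
        raise ValueError("IC50 estimation needs at least 2 concentrations")
    conc = curve["concentration"].to_numpy(dtype=float)
    sr = curve["sr_percent"].to_numpy(dtype=float)
    if method == "interpolate":
        return _ic50_interpolate(conc, sr)
    if method == "four_pl":
        return _ic50_four_pl(conc, sr)
    raise ValueError(f"unknown IC50 method {method!r}")
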