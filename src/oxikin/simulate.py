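"""Synthetic data generators with the exact structure the fitters assume.

Each generator is the right-inverse of its fitter: at zero noise,
``fit(generate(theta)) == theta`` to numerical precision, which makes every
fitting stage testable end-to-end without laboratory data.

* Rancimat: IP(T) = exp(Ea/(R T) - ln A) * eps, eps lognormal — the inverse
  of the Arrhenius law with multiplicative noise (induction periods are
  positive and their errors plausibly proportional).
* DSC peaks: Tp(beta) solved from the chosen FWO/KAS linearization itself
  by root-bracketing; the fits only ever see (beta, Tp) pairs, so
  generating from the linearized relation is sufficient and exactly
  invertible.
* Dose-response: a 4PL scavenging curve converted to absorbance pairs with
  the control fixed at A0 = 0.700 (the standard ABTS working absorbance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import CELSIUS_OFFSET, R_J_PER_MOL_K

#: Rancimat temperature grid, K (100-130 C, the standard accelerated range).
DEFAULT_TEMPERATURES_K = tuple(t + CELSIUS_OFFSET for t in (100.0, 110.0, 120.0, 130.0))

#: DSC heating rates, K/min.
DEFAULT_BETAS = (5.0, 10.0, 15.0, 20.0)


@dataclass
class SimulationConfig:
    """Declarative description of one synthetic dataset.

    ``model`` selects the generator; ``parameters`` is passed through as
    keyword arguments. A fixed seed gives byte-identical output.
    """

    seed: int
    model: str  # "rancimat" | "dsc_peaks" | "dose_response"
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("rancimat", "dsc_peaks", "dose_response"):
            raise ValueError(f"unknown simulation model {self.model!r}")


def generate_rancimat(
    ea_kj_mol: float,
    ln_a: float,
    temperatures_K: tuple[float, ...] = DEFAULT_TEMPERATURES_K,
    noise_sigma: float = 0.0,
    sample: str = "synthetic",
    n_replicates: int = 1,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Induction periods from an Arrhenius law with lognormal noise.

    IP(T) = exp(Ea/(R T) - ln A) * eps with ln(eps) ~ N(0, noise_sigma^2);
    noise_sigma = 0 gives exact Arrhenius data.
    """
    temps = np.asarray(temperatures_K, dtype=float)
    if (temps <= 0).any():
        raise ValueError("temperatures must be positive kelvin")
    if ea_kj_mol <= 0 or noise_sigma < 0 or n_replicates < 1:
        raise ValueError("ea_kj_mol > 0, noise_sigma >= 0, n_replicates >= 1 required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        ip = np.exp(ea_kj_mol * 1000.0 / (R_J_PER_MOL_K * temps) - ln_a)
        if noise_sigma > 0:
            ip = ip * np.exp(rng.normal(0.0, noise_sigma, size=temps.shape))
        for T, h in zip(temps, ip):
            rows.append({"sample": sample, "temperature_K": T,
                         "ip_hours": h, "replicate": rep})
    return pd.DataFrame(rows)


def _tp_from_linearized(
    log10_beta: float, tp_term: str, ea_kj_mol: float, c_constant: float, factor: float
) -> float:
    """Solve lg(beta [ / Tp^2]) = -factor * E/(R Tp) + C for Tp by bracketing."""
    e_over_r = ea_kj_mol * 1000.0 / R_J_PER_MOL_K

    def residual(tp: float) -> float:
        lhs = log10_beta - (2.0 * np.log10(tp) if tp_term == "kas" else 0.0)
        return lhs - (-factor * e_over_r / tp + c_constant)

    lo, hi = 200.0, 2000.0
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise ValueError(
            f"no Tp in [{lo}, {hi}] K solves the linearized relation "
            f"(residuals {r_lo:.3g}, {r_hi:.3g}); check E and C"
        )
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=1e-15))


def generate_dsc_peaks(
    ea_kj_mol: float,
    c_constant: float,
    betas: tuple[float, ...] = DEFAULT_BETAS,
    method: str = "fwo",
    sample: str = "synthetic",
) -> pd.DataFrame:
    """Peak temperatures consistent with an FWO or KAS line.

    For each heating rate beta the peak temperature is the root of the
    chosen linearized equation on Tp in [200, 2000] K (|residual| < 1e-10).
    Deterministic — no noise model, matching how these fits are normally
    exercised.
    """
    from .constants import FWO_FACTOR, KAS_FACTOR

    if method not in ("fwo", "kas"):
        raise ValueError(f"method must be 'fwo' or 'kas', got {method!r}")
    betas_arr = np.asarray(betas, dtype=float)
    if (betas_arr <= 0).any():
        raise ValueError("heating rates must be positive")
    factor = FWO_FACTOR if method == "fwo" else KAS_FACTOR
    rows = []
    for beta in betas_arr:
        tp = _tp_from_linearized(np.log10(beta), method, ea_kj_mol, c_constant, factor)
        rows.append({"sample": sample, "beta_K_per_min": float(beta), "tp_K": tp})
    return pd.DataFrame(rows)


def generate_dose_response(
    ic50: float,
    hill: float = 1.5,
    sr_max: float = 100.0,
    concentrations: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    noise_sigma: float = 0.0,
    a0: float = 0.700,
    assay: str = "abts",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """A Hill-type scavenging curve rendered as absorbance pairs.

    SR(c) = sr_max * c^hill / (ic50^hill + c^hill) + N(0, noise_sigma^2),
    then A1 = A0 * (1 - SR/100) with A0 fixed at the working absorbance.
    """
    if ic50 <= 0 or hill <= 0:
        raise ValueError("ic50 and hill must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        sr = np.where(
            conc > 0,
            sr_max * conc**hill / (ic50**hill + conc**hill),
            0.0,
        )
    if noise_sigma > 0:
        sr = sr + rng.normal(0.0, noise_sigma, size=conc.shape)
    a1 = a0 * (1.0 - sr / 100.0)
    return pd.DataFrame(
        {"assay": assay, "concentration": conc, "a0": a0, "a1": a1,
         "sr_percent": sr}
    )


def run_simulation(config: SimulationConfig) -> pd.DataFrame:
    """Dispatch a SimulationConfig to its generator, seeding any randomness."""
    params = dict(config.parameters)
    if config.model == "rancimat":
        return generate_rancimat(seed=config.seed, **params)
    if config.model == "dose_response":
        return generate_dose_response(seed=config.seed, **params)
    return generate_dsc_peaks(**params)
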