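"""CSV readers with schema validation and row-addressed error messages.

Input tables are small (a handful of temperatures or concentrations), so
everything is read eagerly through pandas with string dtype and converted
field by field: an unparseable number or a unit typo is reported with the
row number and column name rather than as a coercion NaN. Decimal commas
are rejected, never guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .rancimat import to_kelvin


class TableValidationError(ValueError):
    """A CSV failed schema validation; the message names row and column."""


@dataclass(frozen=True)
class Column:
    name: str
    convert: Callable[[str], object] | None = None  # None -> keep as text
    required: bool = True
    check: Callable[[object], str | None] = staticmethod(lambda v: None)


def _number(text: str) -> float:
    if "," in text:
        raise ValueError("decimal commas are not accepted; use a period")
    return float(text)


def _positive(v) -> str | None:
    return None if v > 0 else "must be > 0"


def _non_negative(v) -> str | None:
    return None if v >= 0 else "must be >= 0"


def _unit_in(allowed: tuple[str, ...]) -> Callable[[object], str | None]:
    def check(v) -> str | None:
        return None if v in allowed else f"must be one of {allowed}"
    return check


SCHEMAS: dict[str, list[Column]] = {
    "species": [
        Column("label"),
        Column("energy", _number),
        Column("unit", check=_unit_in(("hartree", "kJ_per_mol"))),
        Column("role", check=_unit_in(
            ("parent", "radical", "hydrogen_atom", "orbital_homo", "orbital_lumo"))),
    ],
    "induction_period": [
        Column("sample"),
        Column("temperature", _number, check=_positive),
        Column("temperature_unit", check=_unit_in(("C", "K"))),
        Column("ip_hours", _number, check=_positive),
        Column("replicate", _number, required=False),
    ],
    "dsc_peaks": [
        Column("sample"),
        Column("beta_K_per_min", _number, check=_positive),
        Column("tp", _number, check=_positive),
        Column("tp_unit", check=_unit_in(("C", "K"))),
    ],
    "dose_response": [
        Column("assay", check=_unit_in(("dpph", "abts"))),
        Column("concentration", _number, check=_non_negative),
        Column("a0", _number, check=_positive),
        Column("a1", _number, check=_non_negative),
    ],
    "regression_lines": [
        Column("sample"),
        Column("method", check=_unit_in(("arrhenius", "eyring", "fwo", "kas"))),
        Column("slope", _number),
        Column("intercept", _number),
        Column("r_squared", _number, required=False),
    ],
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Returns a typed DataFrame; temperature-bearing schemas gain a
    ``temperature_K`` / ``tp_K`` column converted from the declared unit.
    Errors name the offending row (1-based, excluding header) and column.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    columns = SCHEMAS[schema]
    missing = [c.name for c in columns if c.required and c.name not in raw.columns]
    if missing:
        raise TableValidationError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(raw.columns)}"
        )
    out: dict[str, list] = {}
    for col in columns:
        if col.name not in raw.columns:
            continue
        values = []
        for i, text in enumerate(raw[col.name], start=1):
            if pd.isna(text):
                raise TableValidationError(
                    f"{path.name}: row {i}, column {col.name!r}: empty value")
            text = str(text).strip()
            if col.convert is not None:
                try:
                    value = col.convert(text)
                except ValueError as exc:
                    raise TableValidationError(
                        f"{path.name}: row {i}, column {col.name!r}: "
                        f"cannot parse {text!r} ({exc})"
                    ) from None
            else:
                value = text
            problem = col.check(value)
            if problem:
                raise TableValidationError(
                    f"{path.name}: row {i}, column {col.name!r}: "
                    f"value {value!r} {problem}"
                )
            values.append(value)
        out[col.name] = values
    df = pd.DataFrame(out)
    if schema == "induction_period":
        df["temperature_K"] = [
            to_kelvin(t, u) for t, u in zip(df["temperature"], df["temperature_unit"])
        ]
    elif schema == "dsc_peaks":
        df["tp_K"] = [to_kelvin(t, u) for t, u in zip(df["tp"], df["tp_unit"])]
    return df
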