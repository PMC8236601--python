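"""Unit handling.

All internal computation is in SI (m, s, kg, mol, Pa, cells). Quantities that
the cardiovascular literature customarily states in mmHg, days or years are
converted at the configuration boundary; the converter accepts ``"value unit"``
strings (e.g. ``"100 mmHg"``, ``"30 year"``).
"""

from __future__ import annotations

MMHG = 133.322          # Pa per mmHg
DAY = 86_400.0          # s per day
YEAR = 365.0 * DAY      # s per (non-leap) year
BOLTZMANN = 1.380649e-23  # J/K
BODY_TEMPERATURE = 310.0  # K

#: multiplicative factors to SI for accepted unit spellings
_FACTORS = {
    "": 1.0,
    "1": 1.0,
    # pressure
    "Pa": 1.0,
    "kPa": 1e3,
    "mmHg": MMHG,
    # time
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "d": DAY,
    "day": DAY,
    "days": DAY,
    "year": YEAR,
    "years": YEAR,
    "yr": YEAR,
    # rates
    "1/s": 1.0,
    "1/d": 1.0 / DAY,
    "1/day": 1.0 / DAY,
    "1/year": 1.0 / YEAR,
    # length
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    # area / volume / flow
    "m^2": 1.0,
    "mm^2": 1e-6,
    "m^3": 1.0,
    "m^3/s": 1.0,
    "mL/s": 1e-6,
    "L/min": 1e-3 / 60.0,
    # viscosity / density / diffusivity
    "Pa.s": 1.0,
    "Pa*s": 1.0,
    "kg/m^3": 1.0,
    "m^2/s": 1.0,
    # concentrations
    "mol/m^3": 1.0,
    "cells/m^3": 1.0,
}


class UnitError(ValueError):
    """Raised for unknown unit spellings in configuration values."""


def parse_quantity(value: object, field: str = "") -> float:
    """Convert a raw number or a ``"value unit"`` string to an SI float.

    Parameters
    ----------
    value
        Either a plain number (assumed SI) or a string such as ``"100 mmHg"``.
    field
        Name used in error messages.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 1:
            try:
                return float(parts[0])
            except ValueError:
                raise UnitError(f"{field or 'value'}: cannot parse {value!r}") from None
        if len(parts) == 2:
            try:
                number = float(parts[0])
            except ValueError:
                raise UnitError(f"{field or 'value'}: cannot parse {value!r}") from None
            unit = parts[1]
            if unit not in _FACTORS:
                raise UnitError(f"{field or 'value'}: unknown unit {unit!r}")
            return number * _FACTORS[unit]
    raise UnitError(f"{field or 'value'}: cannot parse {value!r}")
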