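"""Unit conversions for nitrogen rates.

A rate unit is a string of the form ``"<amount> [N] [<area>] [<time>]"``,
e.g. ``"nmol N cm-2 h-1"`` or ``"mg N m-2 h-1"``. The closed dictionary
covers mol-prefixed amounts (mol..pmol), mass amounts (g..ng, converted via
the molar mass of N), areas per cm2/m2, and per hour/day. Unicode
superscripts and the micro sign are accepted (``µmol N m⁻² d⁻¹``).
Composing a conversion with its inverse is the identity.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .errors import UnitError

_MOLE = {"mol": 1.0, "mmol": 1e-3, "umol": 1e-6, "nmol": 1e-9, "pmol": 1e-12}
_MASS = {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "ng": 1e-9}
_AREA = {"m-2": 1e0, "cm-2": 1e4}   # factor -> canonical "per m2"
_TIME = {"d-1": 1.0, "h-1": 24.0}   # factor -> canonical "per day"

_NORMALIZE = str.maketrans({"µ": "u", "μ": "u", "⁻": "-", "²": "2", "¹": "1"})


def _parse(units: str):
    """Split a unit string into (amount_factor, is_mass, area_factor, time_factor)."""
    tokens = units.translate(_NORMALIZE).split()
    if not tokens:
        raise UnitError("empty unit string")
    amount = tokens[0]
    rest = tokens[1:]
    if rest and rest[0].upper() == "N":
        rest = rest[1:]
    if amount in _MOLE:
        amount_factor, is_mass = _MOLE[amount], False
    elif amount in _MASS:
        amount_factor, is_mass = _MASS[amount], True
    else:
        raise UnitError(f"unknown amount unit {amount!r} in {units!r}")
    area_factor = time_factor = None
    for tok in rest:
        if tok in _AREA and area_factor is None:
            area_factor = _AREA[tok]
        elif tok in _TIME and time_factor is None:
            time_factor = _TIME[tok]
        else:
            raise UnitError(f"unknown or repeated unit token {tok!r} in {units!r}")
    return amount_factor, is_mass, area_factor, time_factor


def convert_units(value, from_units: str, to_units: str,
                  constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert a rate between two unit strings from the closed dictionary.

    Mass and mole amounts interconvert through ``constants.molar_mass_n``;
    the area/time structure of the two units must match (a per-area rate
    cannot silently become a per-vial rate).
    """
    f_amt, f_mass, f_area, f_time = _parse(from_units)
    t_amt, t_mass, t_area, t_time = _parse(to_units)
    if (f_area is None) != (t_area is None) or (f_time is None) != (t_time is None):
        raise UnitError(f"dimensionally incompatible units: {from_units!r} -> {to_units!r}")
    v = np.asarray(value, dtype=float) * f_amt
    if f_mass and not t_mass:
        v = v / constants.molar_mass_n
    elif t_mass and not f_mass:
        v = v * constants.molar_mass_n
    if f_area is not None:
        v = v * (f_area / t_area)
    if f_time is not None:
        v = v * (f_time / t_time)
    v = v / t_amt
    return v if v.ndim else float(v)
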