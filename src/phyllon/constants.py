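"""Physical constants for nitrogen isotope calculations.

The delta scale for nitrogen is anchored to atmospheric N2, whose 15N/14N
ratio is taken as 0.0036765 (equivalent to 0.36630 atom% 15N). All
delta <-> atom% conversions in :mod:`phyllon.tracer` go through an
:class:`IsotopeConstants` instance so a non-default reference can be used.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference ratio of the delta-15N air scale and the molar mass of N.

    Attributes
    ----------
    r_air_15n : float
        15N/14N isotope ratio of atmospheric N2 (dimensionless).
    molar_mass_n : float
        Molar mass of nitrogen in g mol-1, used for mass <-> mole
        conversions of tissue N.
    """

    r_air_15n: float = 0.0036765
    molar_mass_n: float = 14.0067

    def __post_init__(self) -> None:
        if not self.r_air_15n > 0:
            raise ValueError(f"r_air_15n must be positive, got {self.r_air_15n}")
        if not 13.9 < self.molar_mass_n < 14.1:
            raise ValueError(
                f"molar_mass_n must lie in (13.9, 14.1) g/mol, got {self.molar_mass_n}"
            )

    @property
    def atom_pct_air(self) -> float:
        """Natural-abundance atom% 15N implied by the air ratio (~0.36630)."""
        return 100.0 * self.r_air_15n / (1.0 + self.r_air_15n)


DEFAULT_CONSTANTS = IsotopeConstants()
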