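"""Unit bookkeeping for microdosimetric dose conversion.

Single source of truth for the constant that turns a specific-energy-like
quantity expressed in keV per (g/cm^3 * um^3) into gray.  It closes the
dimensions of the MKM alpha term  beta * ybar* / (rho * pi * rd^2):

    1 keV                 = 1.602176634e-16 J     (exact, SI 2019)
    1 um^3 at 1 g/cm^3    = 1e-15 kg
    => 1 keV / (g/cm^3 * um^3) = 0.1602176634 Gy
"""

_JOULE_PER_KEV = 1.602176634e-16
_KG_PER_UM3_AT_UNIT_DENSITY = 1e-15

#: Gy per keV/(g cm^-3 um^3)
KEV_PER_UM3_TO_GY = _JOULE_PER_KEV / _KG_PER_UM3_AT_UNIT_DENSITY


def unit_conversion_constant() -> float:
    """Return the dose conversion constant, 0.1602176634 Gy per keV/(g cm^-3 um^3)."""
    return KEV_PER_UM3_TO_GY
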