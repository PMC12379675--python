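"""Physical constants and unit helpers.

Single source of truth for the CODATA constants used throughout the
package.  Internal unit convention: energies in MeV, lengths in mm for
public stopping/range results (cm internally where electron densities
are involved), number densities in cm^-3, cross sections in mb
(1 mb = 1e-27 cm^2), times in seconds.
"""

from __future__ import annotations

# CODATA 2018
M_E_C2 = 0.51099895  # electron rest energy, MeV
R_E = 2.8179403262e-13  # classical electron radius, cm
N_A = 6.02214076e23  # Avogadro constant, mol^-1
Q_E = 1.602176634e-19  # elementary charge, C

MB_TO_CM2 = 1e-27  # millibarn -> cm^2

#: seconds per unit, for schedule parsing
TIME_UNITS = {
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "d": 86400.0,
    "y": 365.25 * 86400.0,
}


def to_seconds(value: float, unit: str) -> float:
    """Convert a duration to seconds.  Accepted units: s, min, h, d, y."""
    try:
        return float(value) * TIME_UNITS[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_UNITS)}"
        ) from None
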