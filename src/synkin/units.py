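"""Unit conversions, centralised so hours/seconds mixing cannot drift.

The package-wide convention: time is in hours and concentrations in μM at
every interface; seconds and molar appear only inside rate-constant
arithmetic, converted through the helpers here.
"""

S_PER_H = 3600.0
M_PER_UM = 1e-6


def kplus_to_per_uM_per_h(k_plus_M_s: float) -> float:
    """Convert an elongation rate constant from M⁻¹ s⁻¹ to μM⁻¹ h⁻¹."""
    return k_plus_M_s * M_PER_UM * S_PER_H


def hours_to_seconds(t_h: float) -> float:
    return t_h * S_PER_H


def seconds_to_hours(t_s: float) -> float:
    return t_s / S_PER_H
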