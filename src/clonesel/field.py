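"""Small field/weather formulas used when phenotyping heat-stress trials."""

from __future__ import annotations

import numpy as np

__all__ = ["compute_tmean", "specific_gravity"]


def compute_tmean(t9am, t9pm, tmax, tmin):
    """Compensated daily mean temperature (°C).

    Weighted mean of four readings with weight 2 on the 9 p.m. one:
    ``(T9am + 2*T9pm + TMAX + TMIN) / 5``.
    """
    t9am, t9pm, tmax, tmin = map(np.asarray, (t9am, t9pm, tmax, tmin))
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    out = (t9am + 2.0 * t9pm + tmax + tmin) / 5.0
    return float(out) if out.ndim == 0 else out


def specific_gravity(mass_air, mass_water):
    """Tuber specific gravity from hydrostatic weighing.

    ``SG = m_air / (m_air - m_water)``; the denominator is the buoyant
    (displaced-water) mass, so SG > 1 whenever the sample sinks.
    """
    mass_air, mass_water = map(np.asarray, (mass_air, mass_water))
    if np.any(mass_water < 0):
        raise ValueError("mass_water must be nonnegative")
    if np.any(mass_air <= mass_water):
        raise ValueError("mass_air must exceed mass_water (sample must displace water)")
    out = mass_air / (mass_air - mass_water)
    return float(out) if out.ndim == 0 else out
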