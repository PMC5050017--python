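"""Charge/mass bookkeeping for whole-cell pump currents.

These are the back-of-the-envelope quantities the decay analysis leans on:
the apparent cytoplasmic Na mixing volume implied by an initial decay rate,
ATP consumption per liter cytoplasm, total ion movement per liter, and the
sarcolemmal pump surface density implied by a current density and turnover
rate.  All functions are pure and unit-explicit (suffixes on argument
names); physical constants are fixed module constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO_PER_MOL = 6.02214076e23
FARADAY_C_PER_MOL = ELEMENTARY_CHARGE_C * AVOGADRO_PER_MOL  # 96485.33 C/mol

__all__ = [
    "ELEMENTARY_CHARGE_C",
    "AVOGADRO_PER_MOL",
    "FARADAY_C_PER_MOL",
    "MixingVolumeInput",
    "mixing_volume",
    "atp_per_liter",
    "ion_totals",
    "pump_density",
]


@dataclass(frozen=True)
class MixingVolumeInput:
    """Inputs of the mixing-volume estimate.

    I_nA          : absolute pump current (nA)
    Na_mM         : cytoplasmic Na (mM)
    h             : local log-slope of the Na-current relation (~2)
    k_init_per_s  : initial fractional decay rate of the current (s⁻¹)
    na_per_charge : Na ions moved per elementary charge (3 for the pump)
    """

    I_nA: float
    Na_mM: float
    h: float = 2.0
    k_init_per_s: float = math.nan
    na_per_charge: float = 3.0

    def __post_init__(self):
        if self.I_nA <= 0 or self.Na_mM <= 0 or self.h <= 0 or self.na_per_charge <= 0:
            raise DomainError("mixing-volume inputs must be > 0")


def mixing_volume(inp: MixingVolumeInput) -> float:
    """Apparent cytoplasmic volume (pL) in which Na would be depleting.

    If the current decays because pumping drains a well-mixed pool, the
    initial fractional decay rate is ``k_init = h·(dNa/dt)/Na`` with
    ``dNa/dt = na_per_charge·I/(F·V)``; solving for the volume gives
    ``V = na_per_charge·h·I/(F·k_init·Na)``.  Linear in I, inverse in
    k_init and Na.
    """
    k = inp.k_init_per_s
    if not (k > 0):
        raise DomainError("k_init must be > 0")
    v_L = inp.na_per_charge * inp.h * (inp.I_nA * 1e-9) / (
        FARADAY_C_PER_MOL * k * (inp.Na_mM * 1e-3)
    )
    return v_L * 1e12  # L -> pL


def atp_per_liter(I_pA: float, duration_s: float, cell_volume_pL: float) -> float:
    """ATP cleaved (mmol per liter cytoplasm) by a sustained pump current.

    One net elementary charge crosses per cycle and each cycle cleaves one
    ATP, so moles of ATP = I·t/F and the concentration is I·t/(F·V).
    """
    if I_pA < 0 or duration_s <= 0 or cell_volume_pL <= 0:
        raise DomainError("duration and volume must be > 0, current >= 0")
    mol = (I_pA * 1e-12) * duration_s / FARADAY_C_PER_MOL
    return mol / (cell_volume_pL * 1e-12) * 1e3  # mol/L -> mmol/L


def ion_totals(current, stoichiometry: float, volume_pL: float, dt_s: float | None = None) -> float:
    """Total ions moved (mmol per liter) by a current over time.

    ``current`` is either a Trace-like object with ``time_s`` (s) and
    ``i_pApF``/``i_pA`` arrays, a (time_s, i_pA) pair of arrays, or a tuple
    ``(I_pA, duration_s)`` for a constant current.  The charge integral
    ∫|I|dt is converted to ions via the stoichiometry (ions per elementary
    charge) and referred to the stated volume.

    Note: when given a capacitance-normalized trace the caller must scale
    to absolute current first; this function treats the current array as pA.
    """
    if stoichiometry <= 0:
        raise DomainError("stoichiometry must be > 0")
    if volume_pL <= 0:
        raise DomainError("volume must be > 0")
    if isinstance(current, tuple) and len(current) == 2 and np.isscalar(current[0]):
        I_pA, duration_s = current
        charge_C = abs(I_pA) * 1e-12 * duration_s
    else:
        if hasattr(current, "time_s"):
            t = np.asarray(current.time_s, dtype=float)
            i = np.asarray(getattr(current, "i_pA", None) if hasattr(current, "i_pA") else current.i_pApF, dtype=float)
        else:
            t, i = (np.asarray(a, dtype=float) for a in current)
        charge_C = float(np.trapezoid(np.abs(i), t)) * 1e-12
    mol = charge_C / FARADAY_C_PER_MOL * stoichiometry
    return mol / (volume_pL * 1e-12) * 1e3


def pump_density(
    current_density_pApF: float,
    turnover_per_s: float,
    specific_capacitance_uF_cm2: float = 1.0,
    pump_diameter_nm: float = 3.5,
) -> tuple[float, float]:
    """Pump surface density (per µm²) and membrane area fraction.

    The current per unit area is the current density times the specific
    membrane capacitance (1 µF/cm² = 0.01 pF/µm²); each pump contributes
    ``turnover·e`` of current, so density = i_area/(turnover·e).  The area
    fraction assumes circular pumps of the given diameter.
    """
    if current_density_pApF < 0 or turnover_per_s <= 0:
        raise DomainError("turnover must be > 0, current density >= 0")
    if specific_capacitance_uF_cm2 <= 0 or pump_diameter_nm <= 0:
        raise DomainError("capacitance and diameter must be > 0")
    i_area_pA_um2 = current_density_pApF * specific_capacitance_uF_cm2 * 0.01
    per_pump_pA = turnover_per_s * ELEMENTARY_CHARGE_C * 1e12
    density_um2 = i_area_pA_um2 / per_pump_pA
    radius_um = pump_diameter_nm * 1e-3 / 2.0
    area_fraction = density_um2 * math.pi * radius_um ** 2
    return density_um2, area_fraction
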