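"""Ca-EGTA buffer speciation and single-wavelength Fluo-4 calibration.

The buffer model is 1:1 Ca:EGTA mass action with a caller-supplied
*apparent* dissociation constant (pH folded in); free Ca is the exact root
of the binding quadratic, not the bound≈total shortcut.  The dye model is
minimal 1:1 binding with zero Ca-free fluorescence, so the normalized
fluorescence ratio F/F0 saturates at ``(Ca_rest + Kd_dye)/Ca_rest`` — a
hard bound that the inversion refuses to cross.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, SaturationError, ValidationError

__all__ = [
    "BufferMix",
    "DyeCalib",
    "free_ca",
    "dye_ratio_to_ca",
    "dye_ca_to_ratio",
]


@dataclass(frozen=True)
class BufferMix:
    """An EGTA/Ca pipette-solution recipe.

    EGTA_total_mM / Ca_total_mM : total chelator and total calcium
    Kd_app_uM : apparent Ca-EGTA dissociation constant at the working pH
                (default 0.15 µM, a pH-7.4 value; the constant is apparent
                and must be chosen for the experiment's pH)
    """

    EGTA_total_mM: float
    Ca_total_mM: float
    Kd_app_uM: float = 0.15

    def __post_init__(self):
        if self.EGTA_total_mM < 0 or self.Ca_total_mM < 0:
            raise DomainError("total concentrations must be >= 0")
        if self.Kd_app_uM <= 0:
            raise ValidationError("Kd_app must be > 0")

    @property
    def buffered(self) -> bool:
        """True in the well-buffered regime (EGTA in excess of Ca)."""
        return self.EGTA_total_mM >= self.Ca_total_mM


@dataclass(frozen=True)
class DyeCalib:
    """Fluo-4 single-wavelength calibration constants.

    Kd_dye_uM  : Ca dissociation constant of the dye (0.3 µM)
    Ca_rest_uM : resting (background) free Ca defining F0 (0.13 µM)
    """

    Kd_dye_uM: float = 0.3
    Ca_rest_uM: float = 0.13

    def __post_init__(self):
        if self.Kd_dye_uM <= 0 or self.Ca_rest_uM <= 0:
            raise ValidationError("dye Kd and resting Ca must be > 0")

    @property
    def ratio_bound(self) -> float:
        """Maximal admissible F/F0: dye saturation over resting occupancy."""
        return (self.Ca_rest_uM + self.Kd_dye_uM) / self.Ca_rest_uM


def free_ca(mix: BufferMix) -> float:
    """Free Ca (µM) of an EGTA/Ca mixture by exact 1:1 mass action.

    Conservation plus mass action give
    ``Ca_f² + Ca_f·(EGTA_T − Ca_T + Kd) − Kd·Ca_T = 0``; the positive root
    is returned (numerically stable form).  Continuous in all inputs and
    valid also for over-titrated mixes (Ca_T > EGTA_T), where the excess Ca
    stays free.
    """
    egta = mix.EGTA_total_mM * 1e3  # mM -> µM
    ca_t = mix.Ca_total_mM * 1e3
    kd = mix.Kd_app_uM
    if ca_t == 0:
        return 0.0
    b = egta - ca_t + kd
    c = -kd * ca_t
    # positive root of x^2 + b x + c = 0 with c < 0, stable for large |b|
    disc = math.sqrt(b * b - 4 * c)
    if b >= 0:
        return 2 * (-c) / (b + disc)
    return (-b + disc) / 2


def dye_ratio_to_ca(R: float, calib: DyeCalib = DyeCalib()) -> float:
    """Invert a normalized fluorescence ratio F/F0 to peak free Ca (µM).

    With F ∝ Ca/(Ca + Kd) and F0 at resting Ca, the bound occupancy is
    ``f = R·f0`` with ``f0 = Ca_rest/(Ca_rest + Kd)``, and
    ``Ca = Kd·f/(1 − f)``.  Ratios at or beyond the saturation bound raise
    :class:`SaturationError` naming the bound — a ratio the single-site
    model cannot produce is reported, not silently clipped.
    """
    if R < 1:
        raise DomainError("F/F0 must be >= 1 (F0 is the resting fluorescence)")
    bound = calib.ratio_bound
    if R >= bound:
        raise SaturationError(R, bound)
    f0 = calib.Ca_rest_uM / (calib.Ca_rest_uM + calib.Kd_dye_uM)
    f = R * f0
    return calib.Kd_dye_uM * f / (1.0 - f)


def dye_ca_to_ratio(Ca_uM: float, calib: DyeCalib = DyeCalib()) -> float:
    """Forward dye model: free Ca (µM) to normalized fluorescence ratio.

    Exact inverse of :func:`dye_ratio_to_ca` on the valid domain; tends to
    the saturation bound as Ca → ∞.
    """
    if Ca_uM < 0:
        raise DomainError("Ca must be >= 0")
    f0 = calib.Ca_rest_uM / (calib.Ca_rest_uM + calib.Kd_dye_uM)
    f = Ca_uM / (Ca_uM + calib.Kd_dye_uM)
    return f / f0
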