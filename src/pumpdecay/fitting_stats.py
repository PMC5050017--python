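"""Curve fitting and statistical conventions of the decay analysis.

Hill fits of Na concentration-response data, the single-site hyperbola
describing the Na dependence of fractional decay, the exact two-point
rescue-hyperbola solve, and the two-standard-deviation outlier
("maverick") rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "HillFit",
    "HyperbolaFit",
    "fit_hill",
    "fit_decay_hyperbola",
    "solve_rescue_hyperbola",
    "filter_mavericks",
]


@dataclass
class HillFit:
    """Result of y = ymax·Na^h/(Na^h + K50^h)."""

    K50: float
    h: float
    ymax: float
    stderr: dict = field(default_factory=dict)
    rss: float = math.nan
    n: int = 0

    def predict(self, Na):
        Na = np.asarray(Na, dtype=float)
        return self.ymax * Na ** self.h / (Na ** self.h + self.K50 ** self.h)

    def to_dict(self) -> dict:
        return {
            "params": {"K50": self.K50, "h": self.h, "ymax": self.ymax},
            "stderr": self.stderr,
            "rss": self.rss,
            "n": self.n,
        }


@dataclass
class HyperbolaFit:
    """Result of a rectangular-hyperbola description.

    For the fractional-decay form the curve is ``amplitude·Kd/(Kd + Na)``;
    for the rescue form it is ``baseline + amplitude·Na/(Na + Kd)``.
    """

    Kd: float
    amplitude: float = 1.0
    baseline: float = 0.0
    stderr: dict = field(default_factory=dict)
    rss: float = math.nan
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "params": {"Kd": self.Kd, "amplitude": self.amplitude, "baseline": self.baseline},
            "stderr": self.stderr,
            "rss": self.rss,
            "n": self.n,
        }


def _as_xy(x, y, min_n: int, what: str):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"{what}: x and y must be equal-length 1-D arrays")
    if np.unique(x).size < min_n:
        raise ValidationError(f"{what}: need at least {min_n} distinct x values")
    return x, y


def fit_hill(Na, y, h_fixed: float | None = None) -> HillFit:
    """Least-squares Hill fit y = ymax·Na^h/(Na^h + K50^h) in linear
    response space with non-negative bounds.

    Recovers noiseless model-generated data exactly (to solver precision).
    Fixing ``h_fixed=1`` reduces to a rectangular hyperbola.  Standard
    errors come from the fit covariance.
    """
    Na, y = _as_xy(Na, y, 3, "fit_hill")
    if np.any(Na < 0):
        raise DomainError("Na must be >= 0")
    if np.ptp(y) == 0:
        raise FitError("degenerate data: all responses equal")
    ymax0 = float(np.max(y))
    k0 = float(np.median(Na[Na > 0])) if np.any(Na > 0) else 1.0

    if h_fixed is None:
        def model(x, k50, h, ymax):
            return ymax * x ** h / (x ** h + k50 ** h)

        p0 = (k0, 1.5, ymax0)
        bounds = ([1e-9, 1e-3, 1e-12], [np.inf, 20.0, np.inf])
        names = ("K50", "h", "ymax")
    else:
        if h_fixed <= 0:
            raise DomainError("h_fixed must be > 0")

        def model(x, k50, ymax):
            return ymax * x ** h_fixed / (x ** h_fixed + k50 ** h_fixed)

        p0 = (k0, ymax0)
        bounds = ([1e-9, 1e-12], [np.inf, np.inf])
        names = ("K50", "ymax")

    try:
        popt, pcov = curve_fit(model, Na, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Hill fit failed: {exc}") from exc
    stderr = _stderr(pcov, names)
    resid = y - model(Na, *popt)
    if h_fixed is None:
        k50, h, ymax = popt
    else:
        k50, ymax = popt
        h = h_fixed
    return HillFit(K50=float(k50), h=float(h), ymax=float(ymax),
                   stderr=stderr, rss=float(resid @ resid), n=int(Na.size))


def fit_decay_hyperbola(Na, Fdecay, float_amplitude: bool = False) -> HyperbolaFit:
    """Fit the Na dependence of fractional decay to the single-site vacancy
    hyperbola ``Fdecay = Kd/(Kd + Na)`` (optionally ``A·Kd/(Kd + Na)``)."""
    Na, F = _as_xy(Na, Fdecay, 2, "fit_decay_hyperbola")
    if not np.any(F > 0):
        raise FitError("all fractional decays are <= 0")
    k0 = float(np.median(Na[Na > 0])) if np.any(Na > 0) else 1.0
    if float_amplitude:
        def model(x, kd, a):
            return a * kd / (kd + x)

        p0, bounds, names = (k0, 1.0), ([1e-9, 1e-9], [np.inf, np.inf]), ("Kd", "amplitude")
    else:
        def model(x, kd):
            return kd / (kd + x)

        p0, bounds, names = (k0,), ([1e-9], [np.inf]), ("Kd",)
    try:
        popt, pcov = curve_fit(model, Na, F, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"decay-hyperbola fit failed: {exc}") from exc
    resid = F - model(Na, *popt)
    return HyperbolaFit(
        Kd=float(popt[0]),
        amplitude=float(popt[1]) if float_amplitude else 1.0,
        stderr=_stderr(pcov, names),
        rss=float(resid @ resid),
        n=int(Na.size),
    )


def solve_rescue_hyperbola(
    baseline: float, points: tuple[tuple[float, float], tuple[float, float]]
) -> HyperbolaFit:
    """Exact rescue-hyperbola through two (Na, I) points above a baseline.

    The peak current in Na-free solution defines the baseline of
    ``I = baseline + A·Na/(Na + Kd)``; two measurements at higher Na pin Kd
    and A algebraically:

    ``Kd = Na1·Na2·(y2 - y1)/(y1·Na2 - y2·Na1)`` with ``y = I - baseline``,
    then ``A = y1·(Na1 + Kd)/Na1``.  Symmetric in the two points.
    """
    (na1, i1), (na2, i2) = points
    if na1 == na2:
        raise DomainError("the two Na concentrations must differ")
    if na1 <= 0 or na2 <= 0:
        raise DomainError("Na concentrations must be > 0")
    y1, y2 = i1 - baseline, i2 - baseline
    if y1 <= 0 or y2 <= 0:
        raise DomainError("both currents must exceed the baseline")
    denom = y1 * na2 - y2 * na1
    num = na1 * na2 * (y2 - y1)
    if denom == 0 or num == 0:
        raise DomainError(
            "points are collinear with the origin (flat or proportional); "
            "no finite positive Kd exists"
        )
    kd = num / denom
    if kd <= 0:
        raise DomainError(
            f"inconsistent points: implied Kd = {kd:g} <= 0 "
            f"(currents must saturate with Na)"
        )
    amp = y1 * (na1 + kd) / na1
    if amp <= 0:
        raise DomainError(f"inconsistent points: implied amplitude {amp:g} <= 0")
    return HyperbolaFit(Kd=float(kd), amplitude=float(amp), baseline=float(baseline),
                        rss=0.0, n=2)


def filter_mavericks(values) -> tuple[list, list]:
    """Single-pass two-standard-deviation outlier rule.

    Mean and sample SD are computed once on the full set; values deviating
    from the mean by more than 2·SD are removed.  Requires n >= 3.
    """
    vals = [float(v) for v in values]
    if len(vals) < 3:
        raise ValidationError("maverick filtering requires at least 3 values")
    arr = np.asarray(vals)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0:
        return vals, []
    kept, removed = [], []
    for v in vals:
        (removed if abs(v - mean) > 2 * sd else kept).append(v)
    return kept, removed


def _stderr(pcov: np.ndarray, names: tuple[str, ...]) -> dict:
    with np.errstate(invalid="ignore"):
        errs = np.sqrt(np.diag(pcov))
    return {n: float(e) for n, e in zip(names, errs)}
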