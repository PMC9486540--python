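"""Dose-response support: percent hemolysis, 4PL fitting and back-interpolation.

The complement hemolysis assays read absorbance at 405 nm and express lysis as

    % hemolysis = 100 * (A_test - A_0%) / (A_100% - A_0%)

against water (100% lysis) and buffer (0% lysis) controls.  Antibody titration
curves and immunoassay standard curves are fitted with the four-parameter
logistic (4PL) model

    y(x) = bottom + (top - bottom) / (1 + (x / x_half)^hill)

where ``x_half`` is the inflection concentration (reported as EC50 or IC50
depending on assay direction) and ``hill`` the slope; with ``top > bottom``
the response decreases with x for ``hill > 0`` and increases for ``hill < 0``.
Unknown sample concentrations are recovered by inverting the fitted curve and
multiplying by the dilution factor; observations outside the asymptote range
are flagged as below/above the detection range rather than extrapolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "percent_hemolysis",
    "four_pl",
    "fit_4pl",
    "interpolate_concentration",
    "DoseResponseCurve",
    "InterpolationResult",
    "FitError",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; message carries solver diagnostics."""


def percent_hemolysis(a_test, a_0pct, a_100pct):
    """Percent hemolysis from A405 readings against the 0%/100% lysis controls.

    Affine-invariant in the absorbances; may slightly exceed [0, 100] for
    noisy inputs (not clipped).  Accepts scalars or arrays for ``a_test``.
    """
    a_0pct = float(a_0pct)
    a_100pct = float(a_100pct)
    if not (math.isfinite(a_0pct) and math.isfinite(a_100pct)):
        raise ValueError("control absorbances must be finite")
    if a_100pct <= a_0pct:
        raise ValueError(
            f"degenerate lysis controls: A_100% ({a_100pct}) must exceed A_0% ({a_0pct})"
        )
    a_test = np.asarray(a_test, dtype=float)
    out = 100.0 * (a_test - a_0pct) / (a_100pct - a_0pct)
    return float(out) if out.ndim == 0 else out


def four_pl(x, bottom: float, top: float, x_half: float, hill: float):
    """Evaluate the four-parameter logistic curve at concentration(s) x > 0."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / x_half) ** hill)


@dataclass
class DoseResponseCurve:
    """A concentration series with its fitted 4PL parameters."""

    x: np.ndarray
    y: np.ndarray
    bottom: float
    top: float
    x_half: float  #: inflection concentration (EC50/IC50 depending on direction)
    hill: float
    rss: float  #: residual sum of squares (weighted if a weighting was used)
    weighting: str = "none"
    top_fixed: bool = False
    n_points: int = field(init=False)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.n_points = self.x.size
        if self.x_half <= 0:
            raise ValueError("x_half must be positive")

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.x_half, self.hill)


def _weights(y: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(y)
    if weighting == "inv_y2":
        # 1/y^2 weighting of the squared residuals -> residual scale 1/|y|;
        # guard near-zero responses with a floor at 1% of the response span.
        floor = max(1e-12, 0.01 * float(np.ptp(y)))
        return 1.0 / np.maximum(np.abs(y), floor)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_4pl(
    x,
    y,
    weighting: str = "none",
    fix_top: float | None = None,
) -> DoseResponseCurve:
    """Least-squares 4PL fit of response y against concentration x.

    ``weighting="inv_y2"`` applies the 1/y^2 weighting commonly used for
    immunoassay standard curves.  ``fix_top`` pins the upper plateau (for
    inhibition curves known to reach 100%); the remaining three parameters are
    fitted.  The inflection is optimized on a log scale so it stays positive.
    Needs at least 5 points spanning the transition; a constant response is a
    degenerate input and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 5:
        raise ValueError("need at least 5 points for a 4PL fit")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if (x <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.ptp(y) == 0:
        raise ValueError("constant response: no transition to fit")

    w = _weights(y, weighting)
    # direction: decreasing response -> hill > 0 under this parameterization
    increasing = np.corrcoef(np.log(x), y)[0, 1] > 0
    hill0 = -1.0 if increasing else 1.0
    bottom0, top0 = float(np.min(y)), float(np.max(y))
    log_xhalf0 = float(np.median(np.log(x)))  # geometric median of x

    if fix_top is None:
        def resid(p):
            b, t, lxh, h = p
            return (four_pl(x, b, t, math.exp(lxh), h) - y) * w

        p0 = [bottom0, top0, log_xhalf0, hill0]
    else:
        def resid(p):
            b, lxh, h = p
            return (four_pl(x, b, fix_top, math.exp(lxh), h) - y) * w

        p0 = [bottom0, log_xhalf0, hill0]

    sol = least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    if not sol.success:
        raise FitError(f"4PL fit did not converge: {sol.message} (status {sol.status})")
    if fix_top is None:
        b, t, lxh, h = sol.x
    else:
        b, lxh, h = sol.x
        t = float(fix_top)
    # canonicalize so top >= bottom (the pair (b,t,h) and (t,b,-h) are the
    # same curve); keeps reported asymptotes interpretable
    if t < b:
        b, t, h = t, b, -h
    rss = float(np.sum(sol.fun ** 2))
    return DoseResponseCurve(
        x=x, y=y, bottom=float(b), top=float(t), x_half=float(math.exp(lxh)),
        hill=float(h), rss=rss, weighting=weighting, top_fixed=fix_top is not None,
    )


@dataclass(frozen=True)
class InterpolationResult:
    """Back-interpolated concentration, or a detection-range flag."""

    concentration: float  #: NaN when out of range
    flag: str  #: "ok", "below_detection" or "above_detection"

    @property
    def in_range(self) -> bool:
        return self.flag == "ok"


def interpolate_concentration(
    curve: DoseResponseCurve,
    y_observed: float,
    dilution_factor: float = 1.0,
) -> InterpolationResult:
    """Invert a fitted 4PL curve at an observed response.

    Returns the concentration times the dilution factor.  Responses at or
    beyond the asymptotes cannot be inverted: they are flagged as below or
    above the detection range, where "below" means the response lies beyond
    the low-concentration asymptote of the curve.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    y = float(y_observed)
    if not math.isfinite(y):
        raise ValueError("observed response must be finite")
    b, t, h = curve.bottom, curve.top, curve.hill
    lo, hi = min(b, t), max(b, t)
    if not lo < y < hi:
        # low-x asymptote is top for hill > 0 (decreasing curve), bottom otherwise
        low_x_asymptote = t if h > 0 else b
        if low_x_asymptote == hi:
            flag = "below_detection" if y >= hi else "above_detection"
        else:
            flag = "below_detection" if y <= lo else "above_detection"
        warnings.warn(f"response {y} outside asymptote range ({lo}, {hi})", stacklevel=2)
        return InterpolationResult(float("nan"), flag)
    x = curve.x_half * ((t - b) / (y - b) - 1.0) ** (1.0 / h)
    return InterpolationResult(float(x * dilution_factor), "ok")
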