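"""Fossil-calibration densities: offset lognormals with zero log-mean.

A calibration places a prior on a node age of the form

    age = offset + X,    log X ~ Normal(0, sd**2)

so the 5% and 95% prior quantiles are ``offset + exp(-z * sd)`` and
``offset + exp(z * sd)`` with ``z`` the standard-normal 95% point.  Given
fossil-derived minimum and maximum ages (the two quantiles), the (sd, offset)
pair is recovered uniquely because

    q95 - q05 = exp(z*sd) - exp(-z*sd) = 2 sinh(z*sd)

is strictly increasing in sd.  "Zero mean" refers to the location of the
underlying normal on the log scale; only under that reading do both
parameterizations printed for the same calibration cohere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "Z95",
    "CalibrationDensity",
    "CalibrationQuantiles",
    "quantiles_from_params",
    "params_from_quantiles",
]

#: standard-normal 95% point (the 5% point is its negation)
Z95 = 1.6448536269514722

assert abs(norm.ppf(0.95) - Z95) < 1e-12


class CalibrationQuantiles(NamedTuple):
    """5%/95% quantile ages, unrounded and rounded (2 decimals, half-even)."""

    q05: float
    q95: float
    q05_rounded: float
    q95_rounded: float


@dataclass(frozen=True)
class CalibrationDensity:
    """An offset lognormal calibration with zero log-mean.

    Parameters
    ----------
    sd : float
        Log-scale standard deviation (unitless), > 0.
    offset : float
        Hard minimum age (Mya), >= 0.
    label : str
        Name of the calibrated node.
    """

    sd: float
    offset: float
    label: str = ""

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.offset < 0:
            raise ValueError("offset must be nonnegative")

    @property
    def q05(self) -> float:
        return self.offset + np.exp(-Z95 * self.sd)

    @property
    def q95(self) -> float:
        return self.offset + np.exp(Z95 * self.sd)

    def quantiles(self) -> CalibrationQuantiles:
        return quantiles_from_params(self.sd, self.offset)


def quantiles_from_params(sd: float, offset: float) -> CalibrationQuantiles:
    """5% and 95% quantile ages of the calibration density.

    Returns both unrounded values and values rounded to two decimals with
    half-even (banker's) rounding, the display convention used for fossil
    bounds in Mya.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    q05 = offset + float(np.exp(-Z95 * sd))
    q95 = offset + float(np.exp(Z95 * sd))
    return CalibrationQuantiles(q05, q95, round(q05, 2), round(q95, 2))


def params_from_quantiles(q05: float, q95: float) -> tuple[float, float]:
    """Solve (sd, offset) from fossil-derived 5%/95% quantile ages.

    Eliminating the offset gives ``q95 - q05 = 2 sinh(Z95 * sd)``, solved by
    bracketed root-finding to 1e-10; the offset follows by substitution.
    Round-trips through :func:`quantiles_from_params` to better than 1e-6.

    A solution with negative offset means the fossil bounds are incompatible
    with a nonnegative hard minimum; it is returned with a warning.
    """
    if q95 <= q05:
        raise ValueError("q95 must exceed q05")
    gap = q95 - q05

    def f(sd: float) -> float:
        return 2.0 * np.sinh(Z95 * sd) - gap

    # initial bracket from the closed-form asinh estimate, widened for safety
    sd0 = float(np.arcsinh(gap / 2.0) / Z95)
    lo, hi = sd0 * 0.5, max(sd0 * 2.0, 1e-6)
    while f(lo) > 0:
        lo *= 0.5
    while f(hi) < 0:
        hi *= 2.0
    sd = float(brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))
    offset = q05 - float(np.exp(-Z95 * sd))
    if offset < 0:
        warnings.warn(
            f"quantiles ({q05}, {q95}) imply a negative offset "
            f"({offset:.4g}): fossil bounds are incompatible with a "
            "nonnegative hard minimum age",
            stacklevel=2,
        )
    return sd, offset
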