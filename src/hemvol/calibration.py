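"""Regression calibration of the length-width-depth product.

Ordinary least squares of the reference (planimetry) volume on an A*B*C
product (both in mL) yields a slope/intercept pair that defines a new,
calibrated variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .estimators import VariationSpec

__all__ = ["RegressionFit", "fit_linear_calibration", "derive_variation"]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept_mL: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a calibration fit needs at least 3 cases")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_json(self, **extra: object) -> str:
        payload = {**asdict(self), **extra}
        return json.dumps(payload, sort_keys=True)


def fit_linear_calibration(products, references) -> RegressionFit:
    """OLS of reference volume (y) on product (x), both in mL."""
    x = np.asarray(products, dtype=float)
    y = np.asarray(references, dtype=float)
    if x.shape != y.shape:
        raise ValueError("products and references must have equal length")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("products are constant; slope is undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept_mL=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def derive_variation(
    fit: RegressionFit,
    length_source: str,
    depth_source: str,
    name: str,
) -> VariationSpec:
    """Package a fit as a variation usable by the estimators."""
    return VariationSpec(
        name=name,
        coefficient=fit.slope,
        intercept_mL=fit.intercept_mL,
        length_source=length_source,
        depth_source=depth_source,
    )
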