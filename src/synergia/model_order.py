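"""Model-order selection: the minimum number of synergies.

Rather than thresholding the reconstruction R² directly, the number of
synergies is chosen from the shape of the R²-vs-rank curve: starting from
the full curve, an ordinary least-squares line is fitted and the mean
squared residual computed; if it is not yet below 1e-5 the lowest-rank point
is dropped and the fit repeated, until the residual criterion fires or only
two points remain. The selected order is the first (lowest) rank of the
final, most-linear terminal segment — the rank at which the curve becomes
linear and further synergies stop paying for themselves.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .nmf_core import ModelOrderCurve

#: Mean-squared-error threshold on the linear fit of the R²-vs-rank curve.
MSE_THRESHOLD = 1e-5


def linear_fit_mse(points: Sequence[tuple[float, float]]) -> float:
    """Mean squared residual of the OLS line through (rank, R²) points."""
    pts = list(points)
    if len(pts) < 2:
        raise ValueError(f"need at least 2 points, got {len(pts)}")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(np.mean(resid ** 2))


def select_order(curve: ModelOrderCurve | Sequence[tuple[float, float]],
                 threshold: float = MSE_THRESHOLD) -> int:
    """Pick the minimum number of synergies from an R²-vs-rank curve.

    Iteratively fits a line to the remaining points and drops the first
    point while the mean squared error is >= ``threshold`` (strict
    less-than stops the loop) and more than two points remain. Returns the
    rank of the first point of the final segment.
    """
    pts = curve.points() if isinstance(curve, ModelOrderCurve) else list(curve)
    if len(pts) < 2:
        raise ValueError("curve must contain at least 2 points")
    while True:
        mse = linear_fit_mse(pts)
        if mse < threshold or len(pts) == 2:
            return int(pts[0][0])
        pts = pts[1:]
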