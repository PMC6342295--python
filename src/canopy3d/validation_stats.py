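"""Statistical protocol for validating raster estimates against field data.

Four model families cover the study's comparisons:

* origin-forced linear fit (measured vs estimated volumes): slope
  Σxy/Σx², with the *uncentered* R² = 1 − Σ(y−ŷ)²/Σy² customary for
  through-origin regressions;
* ordinary least squares (height/diameter comparisons): intercept,
  slope, centered R²;
* continuous two-segment ("bilinear") regression with an estimated
  breakpoint, fit by profiled least squares over a breakpoint grid —
  deterministic, with no starting-value sensitivity;
* multiple linear regression with two predictors (daily water stress
  integral and NDVI) plus intercept.

Residuals are measured − estimated, and RMSE uses divisor n (not
n − p) throughout, matching how validation RMSEs are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegressionResult:
    """Fit summary shared by all model families.

    ``slopes`` holds one slope (origin-forced/ordinary), the two
    segment slopes (bilinear), or the predictor coefficients
    (multiple).  ``breakpoint`` is set only by the bilinear fit.
    """

    model: str
    slopes: tuple[float, ...]
    intercept: float
    r2: float
    rmse: float
    n: int
    breakpoint: float | None = None
    identifiable: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        return self.slopes[0]


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return x, y


def residual_rmse(measured, estimated) -> float:
    """Root mean square of (measured − estimated); divisor n."""
    m, e = _clean_xy(measured, estimated)
    if m.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((m - e) ** 2)))


def _centered_r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_origin_forced(x, y) -> RegressionResult:
    """Least-squares line through the origin: slope = Σxy/Σx².

    R² is the uncentered form 1 − Σ(y−ŷ)²/Σy², the convention for
    through-origin fits (the centered form can be negative).
    """
    x, y = _clean_xy(x, y)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all-zero x: origin-forced slope undefined")
    slope = float(np.sum(x * y)) / sxx
    yhat = slope * x
    ss_y = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_y if ss_y > 0 else 1.0
    return RegressionResult(
        model="origin_forced", slopes=(slope,), intercept=0.0,
        r2=r2, rmse=residual_rmse(y, yhat), n=x.size,
        meta={"r2_definition": "uncentered"})


def fit_ordinary(x, y) -> RegressionResult:
    """Ordinary least squares y = a + b·x with centered R²."""
    x, y = _clean_xy(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is constant: slope undefined")
    b, a = np.polyfit(x, y, 1)
    yhat = a + b * x
    return RegressionResult(
        model="ordinary", slopes=(float(b),), intercept=float(a),
        r2=_centered_r2(y, yhat), rmse=residual_rmse(y, yhat), n=x.size)


def fit_bilinear(x, y, grid: np.ndarray | int = 200) -> RegressionResult:
    """Continuous two-segment linear model with estimated breakpoint.

    y = a + b1·x + (b2 − b1)·max(x − c, 0).  For every candidate c on
    the grid (default: 200 points spanning the x-range) the remaining
    parameters are profiled out by least squares; the c minimizing the
    SSE wins.  When the SSE profile is flat (the data are a single
    line) the fit is flagged non-identifiable.
    """
    x, y = _clean_xy(x, y)
    if x.size < 5:
        raise ValueError("need at least 5 points for a bilinear fit")
    if np.isscalar(grid):
        grid = np.linspace(x.min(), x.max(), int(grid))
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < x.min() - 1e-12 or grid.max() > x.max() + 1e-12:
            raise ValueError("breakpoint grid extends outside the x-range")

    # a valid breakpoint needs data on both sides, else the hinge
    # column degenerates (collinear with x or with the constant)
    supported = np.array([(x < c).sum() >= 2 and (x > c).sum() >= 2
                          for c in grid])
    if not supported.any():
        raise ValueError("no breakpoint candidate has ≥2 points per side")
    grid = grid[supported]

    best = None
    sses = np.empty(grid.size)
    for i, c in enumerate(grid):
        design = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        sses[i] = sse
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(c), coef)
    sse, c, coef = best
    a, b1, delta = (float(v) for v in coef)
    yhat = a + b1 * x + delta * np.maximum(x - c, 0.0)
    spread = float(sses.max() - sses.min())
    scale = max(float(np.sum((y - y.mean()) ** 2)), 1e-30)
    identifiable = spread / scale > 1e-9
    return RegressionResult(
        model="bilinear", slopes=(b1, b1 + delta), intercept=a,
        r2=_centered_r2(y, yhat), rmse=residual_rmse(y, yhat), n=x.size,
        breakpoint=c, identifiable=identifiable,
        meta={"grid_size": int(grid.size)})


def fit_multiple(y, X) -> RegressionResult:
    """Multiple linear regression: y = a + b1·X[:,0] + b2·X[:,1].

    Used for the monthly trunk-growth model with daily WSI and NDVI as
    predictors.  Raises on a rank-deficient (collinear) design.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be (n, 2): two predictors")
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X must have equal length")
    if y.size < 4:
        raise ValueError("need at least 4 points")
    design = np.column_stack([np.ones(y.size), X])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: predictors are collinear")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    yhat = design @ coef
    a, b1, b2 = (float(v) for v in coef)
    return RegressionResult(
        model="multiple", slopes=(b1, b2), intercept=a,
        r2=_centered_r2(y, yhat), rmse=residual_rmse(y, yhat), n=y.size)
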