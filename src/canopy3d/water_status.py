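"""Tree water status: the water stress integral and irrigation arithmetic.

Stem water potential (SWP, MPa, always ≤ 0) is measured every 7–10 days
through the dry season.  The water stress integral (WSI) after Myers
accumulates the deviation of SWP from its seasonal maximum (least
negative value) over the measurement window:

    WSI = | Σ_i ( Ψ̄_{i,i+1} − c ) · n_i |            [MPa·d]

where Ψ̄ is the arithmetic mean of two consecutive measurements, c the
maximum SWP inside the window and n_i the interval length in days.  WSI
is reported positive; the companion *daily* WSI is the signed mean
stress level, daily_wsi = −WSI / n_days (MPa, ≤ 0).

Irrigation arithmetic converts effective evapotranspiration to an
orchard water requirement through a crop coefficient Kc and a
ground-cover coefficient Kr, and converts per-hectare volumes to litres
per tree from the planting grid spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SWPSeries:
    """Dated stem water potential measurements for one tree (or plot mean)."""

    tree_id: str
    doy: list[float] = field(default_factory=list)
    swp: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        doy = np.asarray(self.doy, dtype=float)
        swp = np.asarray(self.swp, dtype=float)
        if doy.shape != swp.shape:
            raise ValueError("doy and swp must have equal length")
        if doy.size and np.any(np.diff(doy) <= 0):
            raise ValueError("doy must be strictly increasing")
        if np.any(swp > 0):
            raise ValueError("stem water potential must be ≤ 0 MPa")
        self.doy = doy
        self.swp = swp

    def __len__(self) -> int:
        return self.doy.size


@dataclass
class WSIResult:
    """Water stress integral over a window.

    wsi : MPa·d, ≥ 0 (Myers' absolute-value convention)
    daily_wsi : MPa, ≤ 0; equals −wsi / n_days
    n_days : span of days covered by the measurement intervals
    c_ref : the reference SWP (seasonal maximum inside the window)
    """

    wsi: float
    daily_wsi: float
    n_days: float
    c_ref: float


def water_stress_integral(series: SWPSeries,
                          window: tuple[float, float] = (182.0, 273.0),
                          c_ref: float | None = None) -> WSIResult:
    """Myers' water stress integral of ``series`` over ``window``.

    Records outside the window are ignored (with a warning).  The
    reference c defaults to the per-series seasonal maximum SWP inside
    the window; pass ``c_ref`` to use e.g. a per-treatment reference.
    """
    lo, hi = window
    inside = (series.doy >= lo) & (series.doy <= hi)
    if inside.sum() < len(series):
        warnings.warn(
            f"{int((~inside).sum())} SWP record(s) outside window "
            f"[{lo}, {hi}] ignored", stacklevel=2)
    doy = series.doy[inside]
    swp = series.swp[inside]
    if doy.size < 2:
        raise ValueError("need at least 2 SWP records inside the window")
    c = float(np.max(swp)) if c_ref is None else float(c_ref)
    interval = np.diff(doy)                      # n_i, days
    pair_mean = 0.5 * (swp[:-1] + swp[1:])       # Ψ̄ of consecutive pairs
    signed = float(np.sum((pair_mean - c) * interval))
    wsi = abs(signed)
    n_days = float(doy[-1] - doy[0])
    daily = -wsi / n_days if n_days > 0 else 0.0
    return WSIResult(wsi=wsi, daily_wsi=daily, n_days=n_days, c_ref=c)


@dataclass
class IrrigationParams:
    """Crop/ground-cover coefficients and planting grid of the orchard."""

    kc: float = 0.55
    kr: float = 0.46
    spacing_x: float = 5.0
    spacing_y: float = 5.0

    def __post_init__(self) -> None:
        if min(self.kc, self.kr, self.spacing_x, self.spacing_y) <= 0:
            raise ValueError("all irrigation parameters must be positive")


def irrigation_requirement(et_eff: float, params: IrrigationParams) -> float:
    """Orchard water requirement (mm) from effective ET: et_eff · Kc · Kr."""
    if et_eff < 0:
        raise ValueError("effective evapotranspiration must be ≥ 0")
    return et_eff * params.kc * params.kr


def per_tree_irrigation(volume_per_ha: float, params: IrrigationParams) -> float:
    """Litres per tree from a per-hectare volume (m³ ha⁻¹).

    Divides the hectare volume by the tree density implied by the
    planting grid and converts m³ → L.
    """
    trees_per_ha = 10_000.0 / (params.spacing_x * params.spacing_y)
    return volume_per_ha / trees_per_ha * 1000.0
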