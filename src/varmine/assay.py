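"""Calibration-curve math for colorimetric candidate validation.

Implements the quantification used with a Victoria Blue-style absorbance
assay: an ordinary-least-squares standard curve y = S*c + b, the limit of
detection LOD = 3.3*sigma/S (sigma = residual standard deviation of the
response), back-prediction MAPE, concentration inversion with below-LOD
censoring, fold change at explicit precision, and droplet contact-angle
geometry theta = 2*arctan(H/R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOD_FACTOR = 3.3


@dataclass(frozen=True)
class StandardCurve:
    """A fitted linear calibration model (absorbance vs concentration)."""

    slope: float                  # absorbance per (ug/mL)
    intercept: float              # absorbance
    sigma: float                  # residual SD of the response (n-2 denominator)
    lod: float                    # ug/mL, 3.3*sigma/slope
    mape: float                   # percent, over back-predicted standards
    conc_range: tuple[float, float]
    r_squared: float
    n_points: int

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def summary(self) -> str:
        lo, hi = self.conc_range
        return (f"y = {self.slope:.6g}x + {self.intercept:.6g}  "
                f"(n={self.n_points}, R^2={self.r_squared:.4f}, "
                f"sigma={self.sigma:.3g}, LOD={self.lod:.3g} ug/mL, "
                f"MAPE={self.mape:.3g}%, range {lo:g}-{hi:g} ug/mL)")


@dataclass(frozen=True)
class QuantResult:
    concentration: float
    censored: bool                # below the curve's LOD
    extrapolated: bool = False    # above the calibrated range

    def __str__(self) -> str:
        return "<LOD" if self.censored else f"{self.concentration:.2f}"


@dataclass(frozen=True)
class ContactAngleMeasurement:
    height: float                 # droplet height H
    radius: float                 # base radius R (same unit as H)

    @property
    def theta(self) -> float:
        return contact_angle(self.height, self.radius)


def fit_standard_curve(points: Iterable[tuple[float, float]],
                       sigma_override: float | None = None) -> StandardCurve:
    """Fit y = S*c + b by OLS over (concentration, absorbance) pairs.

    ``sigma_override`` substitutes a blank-replicate standard deviation
    for the residual SD in the LOD (the default).
    """
    pts = [(float(c), float(y)) for c, y in points]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 calibration points, got {len(pts)}")
    conc = np.array([c for c, _ in pts])
    absb = np.array([y for _, y in pts])
    if len(set(conc.tolist())) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.ptp(conc) == 0:
        raise ValueError("zero concentration variance")
    fit = stats.linregress(conc, absb)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {slope:g}")
    residuals = absb - (slope * conc + intercept)
    sigma = float(np.sqrt(np.sum(residuals ** 2) / (len(pts) - 2)))
    sigma_used = sigma if sigma_override is None else float(sigma_override)
    lod = LOD_FACTOR * sigma_used / slope
    back = (absb - intercept) / slope
    nonzero = conc != 0
    mape = (float(np.mean(np.abs(back[nonzero] - conc[nonzero]) / conc[nonzero])) * 100.0
            if nonzero.any() else float("nan"))
    return StandardCurve(slope=slope, intercept=intercept, sigma=sigma_used,
                         lod=lod, mape=mape,
                         conc_range=(float(conc.min()), float(conc.max())),
                         r_squared=float(fit.rvalue ** 2), n_points=len(pts))


def read_calibration_csv(path: str | Path) -> list[tuple[float, float]]:
    """CSV with columns ``concentration, absorbance``."""
    df = pd.read_csv(path)
    return list(zip(df["concentration"].astype(float), df["absorbance"].astype(float)))


def quantify(absorbance: float, curve: StandardCurve) -> QuantResult:
    """Invert the curve: c = (A - b)/S; censored below the LOD."""
    if curve.slope == 0:
        raise ValueError("curve slope is zero")
    conc = (absorbance - curve.intercept) / curve.slope
    return QuantResult(concentration=conc,
                       censored=conc < curve.lod,
                       extrapolated=conc > curve.conc_range[1])


def fold_change(sample_conc: float, reference_conc: float,
                decimals: int | None = None, mode: str = "round") -> float:
    """Concentration ratio at explicit precision.

    ``mode`` is "round" (half-even via Python round) or "truncate"
    (toward zero); exposed because published fold changes mix both
    conventions.
    """
    if reference_conc <= 0:
        raise ValueError("reference concentration must be positive")
    ratio = sample_conc / reference_conc
    if decimals is None:
        return ratio
    if mode == "round":
        return round(ratio, decimals)
    if mode == "truncate":
        factor = 10 ** decimals
        return math.trunc(ratio * factor) / factor
    raise ValueError(f"unknown mode {mode!r}")


def contact_angle(height: float, radius: float) -> float:
    """Droplet contact angle theta = 2*arctan(H/R), in degrees."""
    if radius <= 0:
        raise ValueError("base radius must be positive")
    if height < 0:
        raise ValueError("droplet height must be non-negative")
    return math.degrees(2.0 * math.atan(height / radius))


def quantification_report(samples: Sequence[tuple[str, float]],
                          curve: StandardCurve,
                          reference_id: str | None = None,
                          decimals: int = 2, mode: str = "round") -> pd.DataFrame:
    """Tabulate (sample, absorbance) pairs as concentrations and fold changes."""
    results = {sid: quantify(a, curve) for sid, a in samples}
    ref_conc = None
    if reference_id is not None:
        if reference_id not in results:
            raise KeyError(f"reference sample {reference_id!r} not among samples")
        ref_conc = results[reference_id].concentration
    rows = []
    for sid, absb in samples:
        res = results[sid]
        rows.append({
            "sample": sid,
            "absorbance": absb,
            "concentration": "<LOD" if res.censored else round(res.concentration, 2),
            "extrapolated": res.extrapolated,
            "fold_vs_reference": (
                "" if ref_conc is None
                else fold_change(res.concentration, ref_conc, decimals, mode)),
        })
    return pd.DataFrame(rows, columns=["sample", "absorbance", "concentration",
                                       "extrapolated", "fold_vs_reference"])
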