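"""Non-ML baselines: empirical VI regression and the pixel dichotomy model.

The empirical regression relates a single vegetation index to measured
FVC with a linear (FVC = a*VI + b) or quadratic (FVC = c*VI^2 + d*VI + e)
least-squares fit.  The pixel dichotomy model unmixes each pixel as a
linear combination of a full-vegetation and a bare-soil NDVI endmember:

    FVC = (NDVI - NDVI_s) / (NDVI_v - NDVI_s)

Two endmember presets ship with the package: a literature pair taken
from ecological function-area statistics (0.837 / 0.164) and a pair
derived from the 95% interval of the study-area NDVI distribution
(0.882 / 0.067).  ``estimate_endmembers_ci`` recomputes the latter style
of pair from any NDVI sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VIRegressionModel",
    "EndmemberPair",
    "LITERATURE_ENDMEMBERS",
    "CI95_ENDMEMBERS",
    "fit_vi_regression",
    "predict_vi_regression",
    "estimate_endmembers_ci",
    "pixel_dichotomy",
]


@dataclass(frozen=True)
class VIRegressionModel:
    """Polynomial FVC~VI fit: coefficients in descending power order."""

    vi_name: str
    degree: int
    coefficients: tuple
    r_squared: float | None = None
    rmse: float | None = None

    def __post_init__(self):
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("degree and coefficient count disagree")


@dataclass(frozen=True)
class EndmemberPair:
    """NDVI of pure vegetation / pure soil, with provenance."""

    ndvi_v: float
    ndvi_s: float
    provenance: str = "user"

    def __post_init__(self):
        if not (self.ndvi_v > self.ndvi_s):
            raise ValueError("vegetation endmember must exceed soil endmember")
        if not (-1 <= self.ndvi_s and self.ndvi_v <= 1):
            raise ValueError("endmembers must lie in [-1, 1]")


LITERATURE_ENDMEMBERS = EndmemberPair(0.837, 0.164, provenance="literature")
CI95_ENDMEMBERS = EndmemberPair(0.882, 0.067, provenance="ci95")


def fit_vi_regression(vi, fvc, degree: int = 1, vi_name: str = "VI") -> VIRegressionModel:
    """Least-squares polynomial fit of measured FVC on a vegetation index."""
    vi = np.asarray(vi, dtype=float)
    fvc = np.asarray(fvc, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 (linear) or 2 (polynomial)")
    if vi.shape != fvc.shape or vi.ndim != 1:
        raise ValueError("vi and fvc must be equal-length 1-D arrays")
    if len(vi) < degree + 2:
        raise ValueError(f"need at least {degree + 2} samples for degree {degree}")
    if not (np.all(np.isfinite(vi)) and np.all(np.isfinite(fvc))):
        raise ValueError("inputs must be finite")
    design = np.vander(vi, degree + 1)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("rank-deficient design: vegetation index is (near-)constant")
    coef, *_ = np.linalg.lstsq(design, fvc, rcond=None)
    pred = design @ coef
    resid = fvc - pred
    ss_tot = float(np.sum((fvc - fvc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return VIRegressionModel(vi_name, degree, tuple(coef), r_squared=r2, rmse=rmse)


def predict_vi_regression(model: VIRegressionModel, vi, clip: bool = False):
    """Evaluate a fitted VI regression; optional clamp to [0, 1]."""
    pred = np.polyval(model.coefficients, np.asarray(vi, dtype=float))
    if clip:
        pred = np.clip(pred, 0.0, 1.0)
    return pred


def estimate_endmembers_ci(ndvi, coverage: float = 0.95) -> EndmemberPair:
    """Endmembers as the symmetric tail quantiles of an NDVI sample.

    With the default 95% coverage the soil endmember is the 2.5th and the
    vegetation endmember the 97.5th percentile (linear-interpolation
    quantiles); ``coverage=1`` returns the sample min/max.
    """
    ndvi = np.asarray(ndvi, dtype=float).ravel()
    if ndvi.size < 40:
        raise ValueError("need at least 40 NDVI samples to estimate endmembers")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    tail = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(ndvi, [tail, 1.0 - tail])
    if hi <= lo:
        raise ValueError("degenerate NDVI distribution: endmember quantiles coincide")
    return EndmemberPair(float(hi), float(lo), provenance="ci95")


def pixel_dichotomy(ndvi, pair: EndmemberPair):
    """Linear unmixing of NDVI into FVC, clipped to [0, 1].

    NDVI values outside the endmember interval would map outside [0, 1];
    they are clamped, matching the physical range of a cover fraction.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    fvc = (ndvi - pair.ndvi_s) / (pair.ndvi_v - pair.ndvi_s)
    fvc = np.clip(fvc, 0.0, 1.0)
    return float(fvc) if np.isscalar(ndvi) or ndvi.ndim == 0 else fvc
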