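"""Multi-dimensional feature construction for FVC inversion.

Each observation site carries seven Landsat-8 OLI surface-reflectance
bands (b1 coastal, b2 blue, b3 green, b4 red, b5 NIR, b6 SWIR1,
b7 SWIR2), three topographic factors (DEM, slope, aspect) and 22
vegetation indices derived from the bands.  This module evaluates the
index registry, assembles the 32-column feature table in a fixed order,
and min-max normalises the columns whose values leave [0, 1].

Band semantics default to the standard OLI assignment (b2 = blue,
b3 = green).  ``band_semantics="printed"`` swaps the two, matching
data exported with the alternative labelling sometimes seen in
acquisition tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "BAND_NAMES",
    "TOPO_NAMES",
    "compute_index",
    "build_feature_table",
    "normalize",
    "FeatureTable",
    "FOUR_TYPICAL_VIS",
]

logger = logging.getLogger(__name__)

BAND_NAMES = ["b1", "b2", "b3", "b4", "b5", "b6", "b7"]
TOPO_NAMES = ["dem", "slope", "aspect"]

#: Soil-adjustment factors for SAVI and MNLI.
L1 = 0.5
L2 = 0.5

#: The four indices classically used on their own as FVC drivers.
FOUR_TYPICAL_VIS = ["NDVI", "EVI", "SAVI", "MSAVI"]

#: Tasseled-cap greenness coefficients in band order
#: (blue, green, red, NIR, SWIR1, SWIR2).
_GVI_COEF = (-0.2848, -0.2435, -0.5436, 0.7243, 0.0840, -0.1800)


def _bands(bands, band_semantics: str = "standard"):
    """Unpack a BandVector into named reflectances.

    Accepts a mapping with keys b1..b7 or a length-7 sequence.
    """
    if hasattr(bands, "keys"):
        b = [np.asarray(bands[k], dtype=float) for k in BAND_NAMES]
    else:
        arr = np.asarray(bands, dtype=float)
        if arr.shape[-1] != 7:
            raise ValueError("expected 7 reflectance bands")
        b = [arr[..., i] for i in range(7)]
    if band_semantics == "standard":
        blue, green = b[1], b[2]
    elif band_semantics == "printed":
        green, blue = b[1], b[2]
    else:
        raise ValueError(f"unknown band_semantics {band_semantics!r}")
    # coastal, blue, green, red, nir, swir1, swir2
    return b[0], blue, green, b[3], b[4], b[5], b[6]


def _registry():
    """Index name -> formula, in fixed table order."""

    def ndvi(B, G, R, NIR, S1, S2):
        return (NIR - R) / (NIR + R)

    def evi(B, G, R, NIR, S1, S2):
        return 2.5 * (NIR - R) / (NIR + 6 * R - 7.5 * B + 1)

    def savi(B, G, R, NIR, S1, S2):
        return (1 + L1) * (NIR - R) / (NIR + R + L1)

    def msavi(B, G, R, NIR, S1, S2):
        return (2 * NIR + 1 - np.sqrt((2 * NIR + 1) ** 2 - 8 * (NIR - R))) / 2

    def sr(B, G, R, NIR, S1, S2):
        return NIR / R

    def arvi(B, G, R, NIR, S1, S2):
        rb = 2 * R - B
        return (NIR - rb) / (NIR + rb)

    def dvi(B, G, R, NIR, S1, S2):
        return NIR - R

    def gemi(B, G, R, NIR, S1, S2):
        eta = (2 * (NIR**2 - R**2) + 1.5 * NIR + 0.5 * R) / (NIR + R + 0.5)
        return eta * (1 - 0.25 * eta) - (R - 0.125) / (1 - R)

    def gari(B, G, R, NIR, S1, S2):
        t = 1.7 * (B - R)
        return (NIR - t) / (NIR + t)

    def gdvi(B, G, R, NIR, S1, S2):
        return NIR - G

    def gndvi(B, G, R, NIR, S1, S2):
        return (NIR - G) / (NIR + G)

    def grvi(B, G, R, NIR, S1, S2):
        return NIR / G

    def gvi(B, G, R, NIR, S1, S2):
        c = _GVI_COEF
        return c[0] * B + c[1] * G + c[2] * R + c[3] * NIR + c[4] * S1 + c[5] * S2

    def ipvi(B, G, R, NIR, S1, S2):
        return NIR / (NIR + R)

    def lai(B, G, R, NIR, S1, S2):
        return 3.618 * evi(B, G, R, NIR, S1, S2) - 0.118

    def mnli(B, G, R, NIR, S1, S2):
        return (NIR**2 - R) * (1 + L2) / (NIR**2 + R + L2)

    def msr(B, G, R, NIR, S1, S2):
        ratio = NIR / R
        return (ratio - 1) / (np.sqrt(ratio) + 1)

    def nli(B, G, R, NIR, S1, S2):
        return (NIR**2 - R) / (NIR**2 + R)

    def osavi(B, G, R, NIR, S1, S2):
        return 1.5 * (NIR - R) / (NIR + R + 0.16)

    def rdvi(B, G, R, NIR, S1, S2):
        return (NIR - R) / np.sqrt(NIR + R)

    def tdvi(B, G, R, NIR, S1, S2):
        return np.sqrt(0.5 + (NIR - R) / (NIR + R))

    def vari(B, G, R, NIR, S1, S2):
        return (G - R) / (G + R - B)

    return {
        "NDVI": ndvi,
        "EVI": evi,
        "SAVI": savi,
        "MSAVI": msavi,
        "SR": sr,
        "ARVI": arvi,
        "DVI": dvi,
        "GEMI": gemi,
        "GARI": gari,
        "GDVI": gdvi,
        "GNDVI": gndvi,
        "GRVI": grvi,
        "GVI": gvi,
        "IPVI": ipvi,
        "LAI": lai,
        "MNLI": mnli,
        "MSR": msr,
        "NLI": nli,
        "OSAVI": osavi,
        "RDVI": rdvi,
        "TDVI": tdvi,
        "VARI": vari,
    }


_REGISTRY = _registry()
INDEX_NAMES = list(_REGISTRY)

FEATURE_ORDER = BAND_NAMES + INDEX_NAMES + TOPO_NAMES


def compute_index(name: str, bands, band_semantics: str = "standard"):
    """Evaluate one vegetation index on a BandVector (scalar or vectorised).

    ``bands`` is a mapping with keys b1..b7 or a (..., 7) array of
    reflectances in (0, 1).
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown index {name!r}; known: {INDEX_NAMES}")
    _, blue, green, red, nir, s1, s2 = _bands(bands, band_semantics)
    for arr in (blue, green, red, nir, s1, s2):
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError("reflectances must lie strictly in (0, 1)")
    return _REGISTRY[name](blue, green, red, nir, s1, s2)


@dataclass
class FeatureTable:
    """Site-by-feature matrix with optional min-max normalisation state.

    ``norm`` is None before :func:`normalize`; afterwards it is a frame
    indexed by column name with columns ``min``, ``max`` and a boolean
    ``normalized`` flag recording which columns were rescaled and with
    which fit-row parameters.
    """

    data: pd.DataFrame
    norm: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self):
        return self.data.shape

    def to_csv(self, path) -> None:
        self.data.to_csv(path, float_format="%.10g")
        if self.norm is not None:
            side = str(path)
            side = side[: side.rfind(".")] + "_norm.csv" if "." in side else side + "_norm.csv"
            self.norm.to_csv(side, float_format="%.10g")


def build_feature_table(sites: pd.DataFrame, band_semantics: str = "standard") -> FeatureTable:
    """Assemble the 32-column feature table from a site table.

    Columns, in order: b1..b7, the 22 vegetation indices, dem, slope,
    aspect.  The site table must carry columns b1..b7 and dem/slope/aspect
    (extra columns such as ``fvc`` are ignored).
    """
    if len(sites) == 0:
        raise ValueError("site table is empty")
    for col in BAND_NAMES + TOPO_NAMES:
        if col not in sites.columns:
            raise KeyError(f"site table is missing required column {col!r}")
    bands = {k: sites[k].to_numpy(dtype=float) for k in BAND_NAMES}
    cols = {}
    for b in BAND_NAMES:
        cols[b] = bands[b]
    for name in INDEX_NAMES:
        cols[name] = compute_index(name, bands, band_semantics)
    for t in TOPO_NAMES:
        cols[t] = sites[t].to_numpy(dtype=float)
    data = pd.DataFrame(cols, index=sites.index)
    return FeatureTable(data=data, meta={"band_semantics": band_semantics})


def normalize(table: FeatureTable, fit_rows=None) -> FeatureTable:
    """Min-max rescale the columns whose fit-row values leave [0, 1].

    Parameters are fitted on ``fit_rows`` (positional indices; default all
    rows) and applied to every row, so values outside [0, 1] can appear on
    rows not used for fitting — they are deliberately not clipped.
    Columns already inside [0, 1] on the fit rows are passed through
    unchanged.  A constant out-of-range column maps to 0 with a warning.
    """
    data = table.data
    if fit_rows is None:
        fit = data
    else:
        fit = data.iloc[np.asarray(fit_rows)]
    if len(fit) == 0:
        raise ValueError("fit_rows must be non-empty")
    out = {}
    records = []
    for col in data.columns:
        v_fit = fit[col].to_numpy(dtype=float)
        lo, hi = float(v_fit.min()), float(v_fit.max())
        needs = lo < 0.0 or hi > 1.0
        v = data[col].to_numpy(dtype=float)
        if not needs:
            out[col] = v
        elif hi == lo:
            warnings.warn(f"constant column {col!r} mapped to 0 during normalization")
            out[col] = np.zeros_like(v)
        else:
            out[col] = (v - lo) / (hi - lo)
        records.append((col, lo, hi, needs))
    norm = pd.DataFrame(records, columns=["column", "min", "max", "normalized"]).set_index("column")
    logger.debug("normalized %d/%d columns", int(norm["normalized"].sum()), len(norm))
    return FeatureTable(data=pd.DataFrame(out, index=data.index), norm=norm, meta=dict(table.meta))
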