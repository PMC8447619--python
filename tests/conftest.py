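import numpy as np
import pytest

from fvcinv.synthetic import SiteSimConfig, make_site_table


@pytest.fixture(scope="session")
def site_table():
    """Default 91-site synthetic table (band-space mixing, mild noise)."""
    return make_site_table(SiteSimConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_sites():
    return make_site_table(
        SiteSimConfig(
            band_noise_sd=0.0, soil_brightness_sd=0.0, veg_dem_effect=0.0, seed=7
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def realistic_band_vectors(n, seed=0):
    """Random reflectance 7-vectors that keep every index well-defined.

    Bands are drawn uniformly but constrained to the physically relevant
    regime: NIR above red (land surfaces; keeps TDVI's radicand positive)
    and VARI's denominator (G + R - B) away from zero.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((0, 7))
    while len(out) < n:
        cand = rng.uniform(0.05, 0.95, size=(4 * n, 7))
        g, r, b, nir = cand[:, 2], cand[:, 3], cand[:, 1], cand[:, 4]
        keep = (np.abs(g + r - b) > 0.05) & (r < 0.9) & (nir > r)
        out = np.vstack([out, cand[keep]])
    return out[:n]
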