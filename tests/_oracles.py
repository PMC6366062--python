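"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: brute-force pair counting
for the ROC AUC, a dense-grid level-set area for the FWHM contour, and the
closed-form Gaussian AUC for the limit of detection.
"""

import math

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from csaphantom.phantom_geometry import DIAMETERS_MM, nominal_csa


def brute_force_auc(low, high) -> float:
    """AUC by exhaustive pair counting: wins + half-ties over all pairs."""
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    wins = sum(1.0 for a in low for b in high if b > a)
    ties = sum(1.0 for a in low for b in high if b == a)
    return (wins + 0.5 * ties) / (low.size * high.size)


def halfmax_levelset_area(
    diameter_mm: float, psf_fwhm_mm: float, pixel_mm: float = 0.39, factor: int = 20
) -> float:
    """Area of the half-maximum level set of an imaged disk (mm^2).

    The image-formation model is rendered on a ``factor``-times supersampled
    grid -- indicator disk, pixel-aperture area sampling (a ``pixel_mm`` box
    average), then the Gaussian system PSF -- and thresholded at half its
    maximum.  No contour extraction is involved, so this is an independent
    check of the marching-squares polygon area.
    """
    fine_mm = pixel_mm / factor
    r = diameter_mm / 2.0
    half_width = 2.5 * diameter_mm
    n = 2 * int(round(half_width / fine_mm)) + 1
    ax = (np.arange(n) - n // 2) * fine_mm
    xx, yy = np.meshgrid(ax, ax)
    disk = ((xx**2 + yy**2) <= r**2).astype(float)
    disk = ndimage.uniform_filter(disk, size=factor, mode="constant")
    if psf_fwhm_mm > 0:
        sigma = psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / fine_mm
        disk = ndimage.gaussian_filter(disk, sigma, mode="constant")
    level = disk.max() / 2.0
    above = (disk > level).sum() + 0.5 * (disk == level).sum()
    return float(above) * fine_mm**2


def gaussian_lod_expected(sigma: float, auc_threshold: float = 0.95) -> float:
    """Expected LOD mean when per-diameter CSAs are Gaussian with SD sigma.

    Applies the same per-reference monotone-closure rule as the package, but
    to the exact Gaussian AUC Phi(delta / (sigma * sqrt(2))) instead of
    sampled data, over the drilled diameter grid.
    """
    csas = [nominal_csa(d) for d in DIAMETERS_MM]
    lods = []
    for i in range(len(csas) - 1):
        deltas = [c - csas[i] for c in csas[i + 1 :]]
        passed = [
            norm.cdf(d / (sigma * math.sqrt(2.0))) >= auc_threshold for d in deltas
        ]
        if not passed[-1]:
            continue
        j = len(passed)
        while j > 0 and passed[j - 1]:
            j -= 1
        lods.append(deltas[j])
    return float(np.mean(lods)) if lods else math.nan


def gaussian_table(sigma: float, n_per_diameter: int, seed: int):
    """Synthetic MeasurementTable: CSA ~ N(nominal, sigma^2) per diameter."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for k, d in enumerate(DIAMETERS_MM):
        vals = rng.normal(nominal_csa(d), sigma, n_per_diameter)
        for s, v in enumerate(vals):
            rows.append(
                {
                    "protocol_id": "synthetic",
                    "hole_id": k,
                    "diameter_mm": d,
                    "section_index": s,
                    "csa_mm2": v,
                    "perimeter_mm": np.nan,
                    "circularity": np.nan,
                    "mean_lumen_signal": np.nan,
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)
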