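"""Evaluation statistics for CSA measurements.

* accuracy  -- per-diameter bias, mean(measured) - nominal CSA;
* precision -- per-diameter sample SD of repeated measurements;
* LOD       -- smallest nominal CSA difference whose measurement
  distributions separate with ROC AUC >= 0.95 (Mann-Whitney AUC with ties
  counted 1/2), aggregated over reference diameters with a monotone-closure
  rule;
* SNR       -- mean lumen intensity over background-ROI noise SD;
* circularity summaries and ordinary least-squares regression of measured
  against drilled CSA.

The LOD is indexed by the *nominal* (drilled) CSA difference: the question
answered is "how small a true difference can this protocol tell apart".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom_geometry import PhantomLayout, nominal_csa
from .image_synthesis import SyntheticImageStack, world_to_pixel

__all__ = [
    "MetricSummary",
    "LODResult",
    "RegressionResult",
    "PerformanceSummary",
    "valid_measurements",
    "accuracy",
    "precision",
    "auc",
    "lod",
    "csa_percent",
    "snr",
    "regress",
    "lumen_masks_from_layout",
    "summarize",
]

REFERENCE_DIAMETER_MM = 3.0
#: Rayleigh correction: SD of magnitude noise in a signal-free MR region is
#: sqrt(2 - pi/2) times the underlying Gaussian channel SD.
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


@dataclass
class MetricSummary:
    """A per-diameter metric with its across-diameter mean and SD."""

    mean: float
    sd: float
    per_diameter: pd.Series  # indexed by nominal diameter (mm)


@dataclass
class LODResult:
    """Limit of detection: mean +/- SD over reference diameters.

    ``status`` is "ok" when at least one reference has a defined LOD and
    "undetectable" when even the largest simulated CSA difference fails the
    AUC threshold for every reference.
    """

    lod_mm2_mean: float
    lod_mm2_sd: float
    lod_pct_mean: float
    lod_pct_sd: float
    per_reference: pd.Series  # diameter -> LOD (mm^2), NaN when undefined
    frac_undefined: float
    status: str = "ok"


@dataclass
class RegressionResult:
    slope: float
    intercept_mm2: float
    r2: float
    n: int


@dataclass
class PerformanceSummary:
    """All headline metrics for one protocol condition."""

    protocol_id: str
    accuracy_mean: float
    accuracy_sd: float
    precision_mean: float
    precision_sd: float
    lod_mm2_mean: float
    lod_mm2_sd: float
    lod_pct_mean: float
    lod_pct_sd: float
    snr_mean: float
    snr_sd: float
    circ_mean: float
    circ_sd: float
    n_valid: int
    n_failed: int
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "extra"}
        row.update(self.extra)
        return row


def valid_measurements(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with successful segmentations."""
    return table[table["status"] == "ok"]


# --------------------------------------------------------------------------
# accuracy / precision

def accuracy(table: pd.DataFrame) -> MetricSummary:
    """Per-diameter bias mean(measured) - nominal, summarized across diameters."""
    ok = valid_measurements(table)
    if ok.empty:
        raise ValueError("no valid measurements")
    per = ok.groupby("diameter_mm")["csa_mm2"].mean()
    bias = per - pd.Series({d: nominal_csa(d) for d in per.index})
    return MetricSummary(float(bias.mean()), float(bias.std(ddof=1)), bias)


def precision(table: pd.DataFrame) -> MetricSummary:
    """Per-diameter sample SD (ddof=1), summarized across diameters.

    Diameters with a single valid measurement are excluded with a warning.
    """
    ok = valid_measurements(table)
    if ok.empty:
        raise ValueError("no valid measurements")
    counts = ok.groupby("diameter_mm")["csa_mm2"].count()
    singletons = counts[counts < 2].index
    if len(singletons):
        warnings.warn(f"diameters with <2 valid rows excluded: {list(singletons)}")
    sds = (
        ok[~ok["diameter_mm"].isin(singletons)]
        .groupby("diameter_mm")["csa_mm2"]
        .std(ddof=1)
    )
    return MetricSummary(float(sds.mean()), float(sds.std(ddof=1)), sds)


# --------------------------------------------------------------------------
# ROC AUC and limit of detection

def auc(samples_low, samples_high) -> float:
    """Mann-Whitney AUC: P(high > low) + 1/2 P(high = low).

    Equals the area under the empirical ROC curve separating the two sets;
    antisymmetric, auc(x, y) + auc(y, x) = 1 exactly (ties count one half).
    """
    a = np.asarray(samples_low, dtype=float)
    b = np.asarray(samples_high, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_b = ranks[a.size :].sum()
    u = r_b - b.size * (b.size + 1) / 2.0
    return float(u / (a.size * b.size))


def lod(
    table: pd.DataFrame,
    auc_threshold: float = 0.95,
    min_valid_fraction: float = 0.5,
) -> LODResult:
    """ROC-AUC limit of detection over all reference diameters.

    For each reference diameter d_i, AUC(CSA(d_i), CSA(d_j)) is evaluated for
    every larger diameter d_j.  The per-reference LOD is the smallest nominal
    CSA difference such that that pair *and all larger differences from the
    same reference* reach the AUC threshold (monotone closure).  References
    whose largest available difference fails the threshold get no LOD; the
    summary averages defined LODs and reports the undefined fraction.
    Diameters with fewer than ``min_valid_fraction`` of the modal number of
    valid measurements are dropped as unusable.
    """
    ok = valid_measurements(table)
    groups = {d: g["csa_mm2"].to_numpy() for d, g in ok.groupby("diameter_mm")}
    if len(groups) < 2:
        raise ValueError("need at least two diameters with valid measurements")
    n_max = max(len(v) for v in groups.values())
    diams = sorted(d for d, v in groups.items() if len(v) >= min_valid_fraction * n_max)
    if len(diams) < 2:
        raise ValueError("too few usable diameters after the validity filter")
    csa = {d: nominal_csa(d) for d in diams}

    per_ref: dict[float, float] = {}
    for i, di in enumerate(diams[:-1]):
        comparisons = diams[i + 1 :]
        passed = [auc(groups[di], groups[dj]) >= auc_threshold for dj in comparisons]
        if not passed[-1]:
            per_ref[di] = math.nan  # largest difference not detected
            continue
        # smallest j such that all pairs from j upward pass
        j = len(passed)
        while j > 0 and passed[j - 1]:
            j -= 1
        per_ref[di] = csa[comparisons[j]] - csa[di]
    per = pd.Series(per_ref, dtype=float).sort_index()
    defined = per.dropna()
    frac_undef = 1.0 - len(defined) / len(per) if len(per) else 1.0
    if defined.empty:
        return LODResult(
            math.nan, math.nan, math.nan, math.nan, per, frac_undef,
            status="undetectable",
        )
    pct = defined.apply(csa_percent)
    return LODResult(
        float(defined.mean()),
        float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
        float(pct.mean()),
        float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
        per,
        frac_undef,
    )


def csa_percent(delta_mm2: float, reference_diameter_mm: float = REFERENCE_DIAMETER_MM) -> float:
    """A CSA difference expressed relative to the reference-lumen area (%)."""
    if not reference_diameter_mm > 0:
        raise ValueError("reference diameter must be positive")
    return 100.0 * delta_mm2 / nominal_csa(reference_diameter_mm)


# --------------------------------------------------------------------------
# SNR

def lumen_masks_from_layout(
    stack: SyntheticImageStack,
    layout: PhantomLayout | None = None,
    core_radius_mm: float = 0.5,
) -> dict[int, np.ndarray]:
    """Boolean lumen-core masks (pixels within ``core_radius_mm`` of each
    hole center), safely inside every drilled diameter."""
    layout = layout or stack.layout_ref
    shape = stack.pixels.shape[1:]
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    masks = {}
    for hid, hole in enumerate(layout.holes):
        r, c = np.atleast_1d(
            world_to_pixel(hole.center_xy_mm, shape, stack.pixel_mm)
        ).ravel()
        masks[hid] = (
            np.hypot(rr - r, cc - c) * stack.pixel_mm <= core_radius_mm
        )
    return masks


def snr(
    stack: SyntheticImageStack,
    lumen_masks: dict[int, np.ndarray] | None = None,
    background_roi: tuple[int, int, int, int] | None = None,
) -> tuple[pd.DataFrame, MetricSummary]:
    """Per-hole, per-section SNR = mean lumen intensity / background noise SD.

    For MR magnitude images the background ROI is signal-free, so its SD is
    Rayleigh-distributed; it is divided by sqrt(2 - pi/2) to recover the
    underlying channel noise SD before forming the ratio.
    """
    masks = lumen_masks or lumen_masks_from_layout(stack)
    roi = background_roi or stack.background_roi
    r0, c0, nr, nc = roi
    if nr * nc < 100:
        raise ValueError("background ROI must contain at least 100 pixels")
    rows = []
    for sec in range(stack.n_sections):
        img = stack.pixels[sec]
        sd = float(np.std(img[r0 : r0 + nr, c0 : c0 + nc], ddof=1))
        if sd == 0:
            raise ValueError("zero background SD: noiseless input has no defined SNR")
        if stack.modality == "MR":
            sd = sd / RAYLEIGH_SD_FACTOR
        for hid, mask in masks.items():
            rows.append(
                {
                    "hole_id": hid,
                    "section_index": sec,
                    "snr": float(img[mask].mean()) / sd,
                }
            )
    df = pd.DataFrame(rows)
    per_hole = df.groupby("hole_id")["snr"].mean()
    return df, MetricSummary(
        float(df["snr"].mean()), float(df["snr"].std(ddof=1)), per_hole
    )


# --------------------------------------------------------------------------
# regression

def regress(table: pd.DataFrame) -> RegressionResult:
    """OLS of measured CSA on nominal drilled CSA over all valid rows."""
    ok = valid_measurements(table)
    if ok["diameter_mm"].nunique() < 3:
        raise ValueError("need at least 3 distinct diameters")
    x = ok["diameter_mm"].apply(nominal_csa).to_numpy()
    y = ok["csa_mm2"].to_numpy()
    if np.var(x) == 0:
        raise ValueError("degenerate x variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2), len(x)
    )


# --------------------------------------------------------------------------
# one-call condition summary

def summarize(
    table: pd.DataFrame,
    stack: SyntheticImageStack | None = None,
    protocol_id: str = "",
    auc_threshold: float = 0.95,
) -> PerformanceSummary:
    """Compute the full metric suite for one protocol condition."""
    acc = accuracy(table)
    prec = precision(table)
    det = lod(table, auc_threshold=auc_threshold)
    ok = valid_measurements(table)
    circ = ok["circularity"]
    if stack is not None:
        _, s = snr(stack)
        snr_mean, snr_sd = s.mean, s.sd
    else:
        snr_mean = snr_sd = math.nan
    return PerformanceSummary(
        protocol_id=protocol_id or (table["protocol_id"].iloc[0] if len(table) else ""),
        accuracy_mean=acc.mean,
        accuracy_sd=acc.sd,
        precision_mean=prec.mean,
        precision_sd=prec.sd,
        lod_mm2_mean=det.lod_mm2_mean,
        lod_mm2_sd=det.lod_mm2_sd,
        lod_pct_mean=det.lod_pct_mean,
        lod_pct_sd=det.lod_pct_sd,
        snr_mean=snr_mean,
        snr_sd=snr_sd,
        circ_mean=float(circ.mean()),
        circ_sd=float(circ.std(ddof=1)),
        n_valid=int(len(ok)),
        n_failed=int(len(table) - len(ok)),
        extra={"lod_status": det.status, "lod_frac_undefined": det.frac_undefined},
    )
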