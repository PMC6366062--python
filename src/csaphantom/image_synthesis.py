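"""Synthetic CT-like and MR-like imaging of the resolution phantom.

The imaging chain is deliberately first-order: a noiseless sub-pixel coverage
field of the drilled holes is blurred by an isotropic Gaussian system PSF,
optionally blurred further by the occupancy kernel of a sinusoidal rigid
motion integrated over the protocol's acquisition window, scaled to the
protocol's contrast, and corrupted by protocol-scaled noise (stationary
Gaussian for CT, unit-SD Rician magnitude for MR).  Scanner reconstruction
internals (filtered backprojection, iterative reconstruction, radial
regridding) are represented only through their net effect on noise SD and
blur; this is sufficient for the background-SD noise definition and FWHM
segmentation that the evaluation metrics rely on.

Contrast and noise defaults:

* CT lumen-background contrast is a lookup over (iodine %, tube potential):
  170/260/330/390 HU at 120 kVp and 250/370/460/560 HU at 100 kVp for
  3/4/5/6% iodine.
* CT noise SD scales as 1/sqrt(dose) from a reference SD at 20 mGy, with a
  tube-potential factor and an iterative-reconstruction strength factor
  (1.00 / 0.70 / 0.40 for 0 / 50 / 90%).
* MR signal is the target SNR for the gadolinium concentration (background
  PMMA gives no MR signal), against unit-SD Rician noise.

Coordinates: pixel (row, col) with the block center at the image center and
row index increasing with +y; all physical quantities are in mm via
``pixel_mm``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, signal

from .phantom_geometry import PhantomLayout

__all__ = [
    "DELTA_HU",
    "ASIRV_NOISE_FACTOR",
    "KVP_NOISE_FACTOR",
    "CTDI_REF_MGY",
    "DEFAULT_MR_SNR",
    "CTProtocol",
    "MRProtocol",
    "MotionState",
    "SyntheticImageStack",
    "rasterize_layout",
    "motion_density_kernel",
    "simulate_ct_stack",
    "simulate_mr_cine",
    "find_background_roi",
    "save_stack",
    "load_stack",
]

#: Lumen-minus-background contrast in HU by (iodine %, tube potential kVp).
DELTA_HU: dict[tuple[int, int], float] = {
    (3, 120): 170.0, (4, 120): 260.0, (5, 120): 330.0, (6, 120): 390.0,
    (3, 100): 250.0, (4, 100): 370.0, (5, 100): 460.0, (6, 100): 560.0,
}

#: Noise-SD multiplier for iterative-reconstruction strength (%).
ASIRV_NOISE_FACTOR: dict[int, float] = {0: 1.00, 50: 0.70, 90: 0.40}

#: Noise-SD multiplier for tube potential at matched dose (lower kVp is noisier).
KVP_NOISE_FACTOR: dict[int, float] = {120: 1.00, 100: 1.12}

#: Reference dose at which ``noise_sd_ref_hu`` is specified.
CTDI_REF_MGY = 20.0

#: Default gadolinium concentration (mmol/L) -> target SNR map.  Anchored at
#: SNR ~22 for 0.17 mmol/L and ~73.5 for 1.66 mmol/L; plain water still gives
#: a small but nonzero signal.
DEFAULT_MR_SNR: dict[float, float] = {
    0.00: 8.0, 0.17: 22.0, 0.33: 35.0, 0.50: 45.0,
    0.67: 52.0, 1.00: 64.0, 1.33: 70.0, 1.66: 73.5,
}


@dataclass(frozen=True)
class CTProtocol:
    """CT acquisition/reconstruction condition for the phantom simulation."""

    kvp: int = 100
    ctdi_mgy: float = 20.0
    revolution_s: float = 0.28
    asirv_pct: int = 90
    iodine_pct: int = 6
    pixel_mm: float = 0.39
    section_mm: float = 0.625
    psf_fwhm_mm: float = 0.6
    background_hu: float = 120.0
    noise_sd_ref_hu: float = 18.0
    n_sections: int = 20
    field_of_view_mm: float = 110.0

    def validate(self) -> None:
        if (self.iodine_pct, self.kvp) not in DELTA_HU:
            raise ValueError(
                f"no contrast entry for iodine {self.iodine_pct}% at {self.kvp} kVp"
            )
        if self.asirv_pct not in ASIRV_NOISE_FACTOR:
            raise ValueError(f"unknown reconstruction strength {self.asirv_pct}%")
        if self.section_mm not in (0.625, 5.0):
            raise ValueError("section_mm must be 0.625 or 5.0")
        if self.ctdi_mgy <= 0 or self.revolution_s <= 0:
            raise ValueError("dose and revolution time must be positive")

    @property
    def delta_hu(self) -> float:
        """Lumen contrast for this (iodine, kVp) pair."""
        self.validate()
        return DELTA_HU[(self.iodine_pct, self.kvp)]

    @property
    def noise_sd_hu(self) -> float:
        """Noise SD of a single 0.625-mm section for this condition."""
        self.validate()
        return (
            self.noise_sd_ref_hu
            * math.sqrt(CTDI_REF_MGY / self.ctdi_mgy)
            * KVP_NOISE_FACTOR[self.kvp]
            * ASIRV_NOISE_FACTOR[self.asirv_pct]
        )


@dataclass(frozen=True)
class MRProtocol:
    """Radial cine MR condition; SNR is set by the gadolinium concentration."""

    gd_mmol_l: float = 1.33
    pixel_mm: float = 0.625
    slice_mm: float = 6.5
    tr_ms: float = 4.9
    views_per_segment: int = 19
    radial_views: int = 247
    psf_fwhm_mm: float = 0.8
    target_snr_by_conc: tuple[tuple[float, float], ...] = tuple(
        sorted(DEFAULT_MR_SNR.items())
    )
    n_frames: int = 20
    field_of_view_mm: float = 110.0

    def validate(self) -> None:
        snrs = [s for _, s in sorted(self.target_snr_by_conc)]
        if any(b < a for a, b in zip(snrs, snrs[1:])):
            raise ValueError("target SNR must be non-decreasing in concentration")
        if snrs and snrs[0] <= 0:
            raise ValueError("SNR must be positive even at 0 mmol/L")

    @property
    def target_snr(self) -> float:
        self.validate()
        table = dict(self.target_snr_by_conc)
        if self.gd_mmol_l not in table:
            raise ValueError(
                f"gadolinium concentration {self.gd_mmol_l} mmol/L not in SNR map"
            )
        return table[self.gd_mmol_l]


@dataclass(frozen=True)
class MotionState:
    """Rigid sinusoidal displacement x(t) = A sin(2 pi t / T) along ``axis``.

    Defaults model a 60-bpm rhythm with 15 mm amplitude (30 mm peak-to-peak).
    ``center_time_s`` is the acquisition-window center t'; the default T/4
    places it at the extreme of the excursion where the phantom moves least.
    """

    amplitude_mm: float = 15.0
    period_s: float = 1.0
    axis: tuple[float, float] = (1.0, 0.0)
    center_time_s: float = 0.25

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0 or self.period_s <= 0:
            raise ValueError("amplitude must be >= 0 and period > 0")
        norm = math.hypot(*self.axis)
        if norm == 0:
            raise ValueError("axis must be a nonzero 2-vector")
        object.__setattr__(self, "axis", (self.axis[0] / norm, self.axis[1] / norm))

    def position_mm(self, t) -> np.ndarray:
        return self.amplitude_mm * np.sin(2.0 * np.pi * np.asarray(t) / self.period_s)


@dataclass
class SyntheticImageStack:
    """A simulated stack of sections (CT) or cine frames (MR).

    ``background_roi`` is (row0, col0, n_rows, n_cols) in pixel coordinates,
    guaranteed clear of every hole's blurred support -- the measurement region
    for image noise.
    """

    pixels: np.ndarray  # (n, rows, cols)
    pixel_mm: float
    modality: str  # "CT" | "MR"
    background_roi: tuple[int, int, int, int]
    layout_ref: PhantomLayout
    seed: int
    protocol: CTProtocol | MRProtocol

    @property
    def n_sections(self) -> int:
        return self.pixels.shape[0]

    def mean_image(self) -> np.ndarray:
        if self.n_sections == 0:
            return np.zeros(self.pixels.shape[1:])
        return self.pixels.mean(axis=0)

    def background_pixels(self, section: int | None = None) -> np.ndarray:
        r0, c0, nr, nc = self.background_roi
        if section is None:
            return self.pixels[:, r0 : r0 + nr, c0 : c0 + nc]
        return self.pixels[section, r0 : r0 + nr, c0 : c0 + nc]


# --------------------------------------------------------------------------
# geometry helpers

def image_shape(field_of_view_mm: float, pixel_mm: float) -> tuple[int, int]:
    """Odd image dimensions so the block center falls on a pixel center."""
    n = 2 * int(math.floor(field_of_view_mm / 2.0 / pixel_mm)) + 1
    return (n, n)


def world_to_pixel(xy_mm, shape: tuple[int, int], pixel_mm: float) -> np.ndarray:
    """Block coordinates (x, y) mm -> fractional (row, col) pixel coordinates."""
    xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
    row = xy[:, 1] / pixel_mm + (shape[0] - 1) / 2.0
    col = xy[:, 0] / pixel_mm + (shape[1] - 1) / 2.0
    return np.squeeze(np.column_stack([row, col]))


def pixel_to_world(rc, shape: tuple[int, int], pixel_mm: float) -> np.ndarray:
    rc = np.atleast_2d(np.asarray(rc, dtype=float))
    x = (rc[:, 1] - (shape[1] - 1) / 2.0) * pixel_mm
    y = (rc[:, 0] - (shape[0] - 1) / 2.0) * pixel_mm
    return np.squeeze(np.column_stack([x, y]))


def rasterize_layout(
    layout: PhantomLayout,
    pixel_mm: float,
    supersample: int = 8,
    field_of_view_mm: float | None = None,
) -> np.ndarray:
    """Noiseless coverage field in [0, 1]: per-pixel area fraction inside holes.

    Each pixel is subdivided into ``supersample`` x ``supersample`` points and
    the inside-circle fraction is counted; only the bounding box of each hole
    is visited, so cost is linear in the number of holes.
    """
    if supersample < 4:
        raise ValueError("supersample must be >= 4")
    fov = field_of_view_mm or layout.block_diameter_mm * 1.1
    shape = image_shape(fov, pixel_mm)
    out = np.zeros(shape, dtype=float)
    # sub-pixel offsets at cell centers, in pixel units
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    for hole in layout.holes:
        r_mm = hole.diameter_mm / 2.0
        crow, ccol = np.atleast_1d(
            world_to_pixel(hole.center_xy_mm, shape, pixel_mm)
        ).ravel()
        r_px = r_mm / pixel_mm
        r0 = max(int(math.floor(crow - r_px)) - 1, 0)
        r1 = min(int(math.ceil(crow + r_px)) + 2, shape[0])
        c0 = max(int(math.floor(ccol - r_px)) - 1, 0)
        c1 = min(int(math.ceil(ccol + r_px)) + 2, shape[1])
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        rr = rows[:, None, None, None] + off[None, None, :, None]
        cc = cols[None, :, None, None] + off[None, None, None, :]
        inside = (rr - crow) ** 2 + (cc - ccol) ** 2 <= r_px**2
        out[r0:r1, c0:c1] += inside.mean(axis=(2, 3))
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# motion

def motion_density_kernel(
    motion: MotionState, window_s: float, pixel_mm: float, n_samples: int = 20001
) -> np.ndarray:
    """Normalized occupancy histogram of the in-window displacement.

    Positions x(t) are sampled uniformly over the acquisition window centered
    at t', referenced to the window-center position x(t'), and binned at the
    pixel pitch (bins centered on integer pixel offsets).  The central bin of
    the returned kernel is the zero-displacement bin.
    """
    if window_s < 0 or window_s >= motion.period_s:
        raise ValueError("window must satisfy 0 <= window < period")
    if window_s == 0 or motion.amplitude_mm == 0:
        return np.array([1.0])
    t = motion.center_time_s + np.linspace(-window_s / 2, window_s / 2, n_samples)
    disp = motion.position_mm(t) - motion.position_mm(motion.center_time_s)
    kmax = int(math.ceil(np.max(np.abs(disp)) / pixel_mm)) + 1
    edges = (np.arange(-kmax, kmax + 2) - 0.5) * pixel_mm
    hist, _ = np.histogram(disp, bins=edges)
    kern = hist / hist.sum()
    return kern


def _motion_kernel_2d(kern1d: np.ndarray, axis: tuple[float, float]) -> np.ndarray:
    """Splat the 1-D displacement kernel along an arbitrary axis in 2-D.

    Bin k of ``kern1d`` sits at pixel offset k * axis (bilinear deposition);
    for axis-aligned motion this reduces exactly to the 1-D kernel.
    """
    n = len(kern1d)
    center = n // 2
    half = int(math.ceil(center * max(abs(axis[0]), abs(axis[1])))) + 1
    size = 2 * half + 1
    out = np.zeros((size, size))
    for k, w in enumerate(kern1d):
        if w == 0:
            continue
        # axis = (ax, ay) in block coords; +y is +row
        dc = (k - center) * axis[0]
        dr = (k - center) * axis[1]
        r = dr + half
        c = dc + half
        r0, c0 = int(math.floor(r)), int(math.floor(c))
        fr, fc = r - r0, c - c0
        out[r0, c0] += w * (1 - fr) * (1 - fc)
        out[r0 + 1, c0] += w * fr * (1 - fc)
        out[r0, c0 + 1] += w * (1 - fr) * fc
        out[r0 + 1, c0 + 1] += w * fr * fc
    return out


def _blur(field: np.ndarray, psf_fwhm_mm: float, pixel_mm: float,
          motion: MotionState | None, window_s: float) -> np.ndarray:
    """Apply system PSF and (optionally) the motion occupancy kernel."""
    out = field
    if psf_fwhm_mm > 0:
        sigma_px = psf_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / pixel_mm
        out = ndimage.gaussian_filter(out, sigma_px, mode="constant")
    if motion is not None and motion.amplitude_mm > 0 and window_s > 0:
        k1 = motion_density_kernel(motion, window_s, pixel_mm)
        k2 = _motion_kernel_2d(k1, motion.axis)
        out = signal.fftconvolve(out, k2, mode="same")
    return out


# --------------------------------------------------------------------------
# background ROI

def find_background_roi(
    layout: PhantomLayout,
    pixel_mm: float,
    shape: tuple[int, int],
    psf_fwhm_mm: float,
    roi_mm: float = 12.0,
) -> tuple[int, int, int, int]:
    """Square noise-measurement ROI in an image corner, clear of all holes.

    The simulated background is statistically stationary, so the ROI is
    placed in the corner of the field of view (outside the hole pattern,
    mirroring noise ROIs placed in signal-free surroundings) and checked
    against every hole disk dilated by 3 x the PSF FWHM.
    """
    m = max(int(round(roi_mm / pixel_mm)), 10)
    m = min(m, shape[0] // 4)
    for r0, c0 in (
        (1, 1),
        (1, shape[1] - m - 1),
        (shape[0] - m - 1, 1),
        (shape[0] - m - 1, shape[1] - m - 1),
    ):
        if _roi_clear(layout, pixel_mm, shape, psf_fwhm_mm, (r0, c0, m, m)):
            return (r0, c0, m, m)
    raise RuntimeError("no hole-free background ROI found")


def _roi_clear(layout, pixel_mm, shape, psf_fwhm_mm, roi) -> bool:
    r0, c0, nr, nc = roi
    clearance_mm = 3.0 * psf_fwhm_mm
    for hole in layout.holes:
        hr, hc = np.atleast_1d(
            world_to_pixel(hole.center_xy_mm, shape, pixel_mm)
        ).ravel()
        # distance from hole center to the ROI rectangle, in mm
        dr = max(r0 - hr, 0.0, hr - (r0 + nr - 1))
        dc = max(c0 - hc, 0.0, hc - (c0 + nc - 1))
        if math.hypot(dr, dc) * pixel_mm < hole.diameter_mm / 2.0 + clearance_mm:
            return False
    return True


# --------------------------------------------------------------------------
# simulators

def simulate_ct_stack(
    layout: PhantomLayout,
    protocol: CTProtocol,
    motion: MotionState | None = None,
    seed: int = 0,
    supersample: int = 8,
) -> SyntheticImageStack:
    """Simulate an axial CT stack of the phantom.

    Sections are independent noise realizations of one blurred 2-D geometry
    (the drilled holes are perpendicular to the sections, so geometry does not
    vary through the block).  5-mm sections are formed by averaging 8
    contiguous 0.625-mm noise realizations, reducing noise SD by sqrt(8).
    """
    protocol.validate()
    cov = rasterize_layout(
        layout, protocol.pixel_mm, supersample, protocol.field_of_view_mm
    )
    window_s = protocol.revolution_s / 2.0  # half-scan data window
    field = _blur(cov, protocol.psf_fwhm_mm, protocol.pixel_mm, motion, window_s)
    signal_img = protocol.background_hu + protocol.delta_hu * field
    rng = np.random.default_rng(seed)
    shape = signal_img.shape
    sd = protocol.noise_sd_hu
    if protocol.section_mm == 5.0:
        noise = rng.normal(0.0, 1.0, (protocol.n_sections, 8) + shape).mean(axis=1)
    else:
        noise = rng.normal(0.0, 1.0, (protocol.n_sections,) + shape)
    pixels = signal_img[None] + sd * noise
    roi = find_background_roi(layout, protocol.pixel_mm, shape, protocol.psf_fwhm_mm)
    return SyntheticImageStack(
        pixels=pixels,
        pixel_mm=protocol.pixel_mm,
        modality="CT",
        background_roi=roi,
        layout_ref=layout,
        seed=seed,
        protocol=protocol,
    )


def simulate_mr_cine(
    layout: PhantomLayout,
    protocol: MRProtocol,
    motion: MotionState | None = None,
    seed: int = 0,
    supersample: int = 8,
    noise_sd: float = 1.0,
    repositioning_jitter_mm: float = 0.0,
) -> SyntheticImageStack:
    """Simulate radial cine MR frames of the phantom.

    The lumen signal equals the target SNR for the protocol's gadolinium
    concentration against unit-SD Rician magnitude noise; PMMA and the
    surroundings give zero signal (the block is invisible on MR).  With
    motion, frames are blurred by the occupancy kernel of the effective
    per-heartbeat window (views_per_segment x TR); ``repositioning_jitter_mm``
    adds a Gaussian beat-to-beat repositioning blur along the motion axis
    (default 0: repositioning is treated as perfect).
    """
    protocol.validate()
    s = protocol.target_snr
    cov = rasterize_layout(
        layout, protocol.pixel_mm, supersample, protocol.field_of_view_mm
    )
    window_s = protocol.views_per_segment * protocol.tr_ms / 1000.0
    field = _blur(cov, protocol.psf_fwhm_mm, protocol.pixel_mm, motion, window_s)
    if (
        motion is not None
        and repositioning_jitter_mm > 0
        and motion.amplitude_mm > 0
    ):
        sig_px = repositioning_jitter_mm / protocol.pixel_mm
        sigma = (sig_px * motion.axis[1], sig_px * motion.axis[0])
        field = ndimage.gaussian_filter(field, sigma, mode="constant")
    signal_img = s * field
    rng = np.random.default_rng(seed)
    shape = signal_img.shape
    if noise_sd > 0:
        n1 = rng.normal(0.0, noise_sd, (protocol.n_frames,) + shape)
        n2 = rng.normal(0.0, noise_sd, (protocol.n_frames,) + shape)
        pixels = np.hypot(signal_img[None] + n1, n2)
    else:
        pixels = np.repeat(signal_img[None], protocol.n_frames, axis=0)
    roi = find_background_roi(layout, protocol.pixel_mm, shape, protocol.psf_fwhm_mm)
    return SyntheticImageStack(
        pixels=pixels,
        pixel_mm=protocol.pixel_mm,
        modality="MR",
        background_roi=roi,
        layout_ref=layout,
        seed=seed,
        protocol=protocol,
    )


# --------------------------------------------------------------------------
# stack I/O

def save_stack(stack: SyntheticImageStack, path, layout_path=None) -> None:
    """Write a stack as multi-page 32-bit TIFF or NIfTI-1, with a JSON sidecar.

    Format is chosen by extension (.tif/.tiff or .nii/.nii.gz).
    """
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, stack.pixels.astype(np.float32))
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([stack.pixel_mm, stack.pixel_mm, 1.0, 1.0])
        img = nib.Nifti1Image(
            np.moveaxis(stack.pixels.astype(np.float32), 0, -1), affine
        )
        nib.save(img, path)
    else:
        raise ValueError(f"unsupported stack format: {path}")
    meta = {
        "pixel_mm": stack.pixel_mm,
        "modality": stack.modality,
        "background_roi": list(stack.background_roi),
        "seed": stack.seed,
        "protocol": asdict(stack.protocol),
        "protocol_class": type(stack.protocol).__name__,
        "layout_csv": str(layout_path) if layout_path else None,
    }
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_stack(path, layout: PhantomLayout | None = None) -> SyntheticImageStack:
    """Read a stack written by :func:`save_stack` (or an external stack with
    the same sidecar layout description)."""
    path = str(path)
    with open(path + ".json") as fh:
        meta = json.load(fh)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        pixels = np.asarray(tifffile.imread(path), dtype=float)
        if pixels.ndim == 2:
            pixels = pixels[None]
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        pixels = np.moveaxis(np.asarray(nib.load(path).dataobj, dtype=float), -1, 0)
    else:
        raise ValueError(f"unsupported stack format: {path}")
    if layout is None:
        if not meta.get("layout_csv"):
            raise ValueError("no layout given and sidecar has no layout_csv")
        layout = PhantomLayout.from_csv(meta["layout_csv"])
    proto_meta = dict(meta["protocol"])
    if meta["protocol_class"] == "CTProtocol":
        protocol: CTProtocol | MRProtocol = CTProtocol(**proto_meta)
    else:
        proto_meta["target_snr_by_conc"] = tuple(
            (float(c), float(s)) for c, s in proto_meta["target_snr_by_conc"]
        )
        protocol = MRProtocol(**proto_meta)
    return SyntheticImageStack(
        pixels=pixels,
        pixel_mm=float(meta["pixel_mm"]),
        modality=meta["modality"],
        background_roi=tuple(meta["background_roi"]),
        layout_ref=layout,
        seed=int(meta["seed"]),
        protocol=protocol,
    )
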