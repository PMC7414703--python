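"""OCTA-like phantoms with known ground truth.

Real widefield OCTA angiograms have (i) a fine capillary speckle texture in
perfused retina, (ii) a handful of large vessels much wider than a capillary,
(iii) slowly varying illumination/contrast differences across the field, and
(iv) contiguous capillary-dropout (ischemic) patches.  The generator emulates
exactly those four ingredients with known ground truth so every pipeline
stage is testable without any acquisition:

* capillary texture — Gaussian-correlated noise (correlation ~2 px)
  re-thresholded to a target vessel fraction;
* large vessels — smooth random-walk tubes of a stated width;
* ischemic patches — unions of overlapping disks where capillaries are
  deleted, placed disjointly and away from large vessels;
* intensity image — high vessel / low tissue means, multiplied by a slowly
  varying illumination field (planar gradient + large smooth blobs) and by
  gamma-distributed multiplicative speckle.

Ground-truth ischemia is defined as the generated patch regions (not "pixels
without vessels"), so scoring is well-posed: sparse capillary gaps in the
perfused texture are not ischemia.  All randomness flows from the single
integer seed in :class:`PhantomSpec` through one ``numpy.random.Generator``;
no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ContractError, GenerationError, ParameterError
from .io import BinaryMask, EnFaceImage
from .pipeline import IschemiaResult

__all__ = ["PhantomSpec", "Phantom", "DetectionScore", "generate_phantom", "score_detection"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic widefield angiogram.

    Defaults emulate the 9 × 15 mm scan at 0.015 mm/px (600 × 1000 raster)
    with a realistic capillary vessel fraction (~0.45), a 30% planar
    illumination gradient plus 15% blob-shaped shading, and speckle with an
    SNR (mean/std) of 5.
    """

    shape_px: tuple[int, int] = (600, 1000)
    pixel_size_mm: float = 0.015
    capillary_density: float = 0.45
    n_large_vessels: int = 4
    large_vessel_width_px: int = 8
    n_ischemic_patches: int = 3
    patch_area_mm2_range: tuple[float, float] = (0.2, 1.0)
    illumination: tuple[float, float] = (0.3, 0.15)
    speckle_snr: float = 5.0
    seed: int = 0
    vessel_intensity: float = 255.0
    tissue_intensity: float = 64.0

    def __post_init__(self) -> None:
        r, c = self.shape_px
        if r < 64 or c < 64:
            raise ParameterError(f"phantom must be at least 64 × 64 px, got {self.shape_px}")
        if not 0 < self.capillary_density < 1:
            raise ParameterError("capillary_density must be in (0, 1)")
        if self.n_large_vessels and self.large_vessel_width_px <= 5:
            raise ParameterError("large vessels must be > 5 px wide to count as large")
        lo, hi = self.patch_area_mm2_range
        if not 0 < lo <= hi:
            raise ParameterError(f"invalid patch area range {self.patch_area_mm2_range}")
        if self.speckle_snr <= 0:
            raise ParameterError("speckle_snr must be > 0")


@dataclass(frozen=True)
class Phantom:
    image: EnFaceImage
    truth_ischemia: BinaryMask
    truth_vessels: BinaryMask
    truth_large_vessels: BinaryMask
    spec: PhantomSpec

    def __post_init__(self) -> None:
        shapes = {
            self.image.shape,
            self.truth_ischemia.shape,
            self.truth_vessels.shape,
            self.truth_large_vessels.shape,
        }
        if len(shapes) != 1:
            raise ContractError(f"phantom rasters disagree in shape: {shapes}")
        if np.any(self.truth_ischemia.astype_bool() & self.truth_vessels.astype_bool()):
            raise ContractError("ischemia and vessel truth masks overlap")


class DetectionScore(NamedTuple):
    dice: float
    recall: float
    precision: float
    n_true_found: int
    n_true_patches: int


def _capillary_texture(rng: np.random.Generator, shape: tuple[int, int], density: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=1.0, mode="reflect")
    thr = np.quantile(smooth, 1.0 - density)
    return smooth > thr


def _large_vessel_tube(
    rng: np.random.Generator, shape: tuple[int, int], width_px: int
) -> np.ndarray:
    """One smooth random-walk tube crossing the image (random orientation)."""
    horizontal = bool(rng.integers(0, 2))
    rows, cols = shape if horizontal else shape[::-1]
    steps = ndimage.gaussian_filter1d(rng.standard_normal(cols), sigma=40.0, mode="reflect")
    path = rng.uniform(0.15, 0.85) * rows + np.cumsum(steps) * 2.0
    path = np.clip(path, width_px, rows - 1 - width_px)
    half = width_px / 2.0
    rr = np.arange(rows)[:, None]
    band = np.abs(rr - path[None, :]) <= half  # width ≈ 2·half + 1 ≥ width_px
    return band if horizontal else band.T


def _blob(rng: np.random.Generator, shape: tuple[int, int], area_px: float) -> np.ndarray:
    """Union of overlapping disks with total area roughly ``area_px``."""
    rows, cols = shape
    r0 = np.sqrt(area_px / np.pi)
    n_disks = int(rng.integers(3, 6))
    margin = int(2 * r0) + 4
    cy = rng.uniform(margin, rows - margin)
    cx = rng.uniform(margin, cols - margin)
    yy, xx = np.ogrid[:rows, :cols]
    blob = np.zeros(shape, dtype=bool)
    # sub-disks of ~70% base radius scattered within ~0.7 r0 of the centre;
    # afterwards the blob is uniformly rescaled to hit the target area
    sub = np.zeros(shape, dtype=bool)
    for _ in range(n_disks):
        oy = cy + rng.uniform(-0.7, 0.7) * r0
        ox = cx + rng.uniform(-0.7, 0.7) * r0
        rr = 0.7 * r0 * rng.uniform(0.8, 1.2)
        sub |= (yy - oy) ** 2 + (xx - ox) ** 2 <= rr**2
    got = sub.sum()
    if got == 0:
        return blob
    # grow/shrink by a morphological distance offset to approach target area
    dist_in = ndimage.distance_transform_edt(sub)
    dist_out = ndimage.distance_transform_edt(~sub)
    sdf = dist_out - dist_in  # negative inside
    # find offset t so that area(sdf <= t) ≈ area_px
    lo_t, hi_t = -r0, r0
    for _ in range(30):
        mid = 0.5 * (lo_t + hi_t)
        if (sdf <= mid).sum() < area_px:
            lo_t = mid
        else:
            hi_t = mid
    blob = sdf <= 0.5 * (lo_t + hi_t)
    return blob


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically build a phantom from its spec (seed → everything)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape_px)
    ps = spec.pixel_size_mm

    vessels = _capillary_texture(rng, shape, spec.capillary_density)

    large = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_large_vessels):
        large |= _large_vessel_tube(rng, shape, spec.large_vessel_width_px)
    vessels |= large

    # ischemic patches: disjoint, away from large vessels (small safety margin)
    forbidden = ndimage.binary_dilation(large, iterations=3) if large.any() else large
    ischemia = np.zeros(shape, dtype=bool)
    lo, hi = spec.patch_area_mm2_range
    for i in range(spec.n_ischemic_patches):
        area_px = rng.uniform(lo, hi) / ps**2
        placed = False
        for _ in range(100):
            blob = _blob(rng, shape, area_px)
            if blob.any() and not (blob & forbidden).any() and not (
                ndimage.binary_dilation(blob, iterations=2) & ischemia
            ).any():
                ischemia |= blob
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place ischemic patch {i + 1}/{spec.n_ischemic_patches} "
                f"disjointly after bounded retries"
            )
    vessels &= ~ischemia

    # intensity: two-level vessel/tissue image × illumination × speckle
    img = np.where(vessels, spec.vessel_intensity, spec.tissue_intensity).astype(np.float64)
    grad_amp, blob_amp = spec.illumination
    rows, cols = shape
    theta = rng.uniform(0, 2 * np.pi)
    yy = np.linspace(-1, 1, rows)[:, None]
    xx = np.linspace(-1, 1, cols)[None, :]
    plane = np.cos(theta) * yy + np.sin(theta) * xx
    plane /= max(np.abs(plane).max(), 1e-12)
    blobs = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 6.0, mode="reflect")
    blobs /= max(np.abs(blobs).max(), 1e-12)
    illum = 1.0 + grad_amp * plane + blob_amp * blobs
    illum = np.clip(illum, 0.2, None)
    k = spec.speckle_snr**2
    speckle = rng.gamma(shape=k, scale=1.0 / k, size=shape)
    pixels = img * illum * speckle

    image = EnFaceImage(
        pixels=pixels,
        pixel_size_mm=ps,
        field_mm=(rows * ps, cols * ps),
        plexus="unspecified",
        source_id=f"phantom(seed={spec.seed})",
    )
    mk = lambda arr, role: BinaryMask(pixels=arr.astype(np.uint8), pixel_size_mm=ps, role=role)
    return Phantom(
        image=image,
        truth_ischemia=mk(ischemia, "ischemia_final"),
        truth_vessels=mk(vessels, "vessel"),
        truth_large_vessels=mk(large, "large_vessel"),
        spec=spec,
    )


def score_detection(result: IschemiaResult, truth: BinaryMask) -> DetectionScore:
    """Pixelwise Dice/recall/precision of the final mask against ground truth.

    ``n_true_found`` counts truth patches (8-connected components) at least
    50% covered by the detection.
    """
    det = result.final_mask.astype_bool()
    tru = truth.astype_bool()
    if det.shape != tru.shape:
        raise ContractError(f"shape mismatch: detection {det.shape} vs truth {tru.shape}")
    inter = float(np.sum(det & tru))
    nd, nt = float(det.sum()), float(tru.sum())
    dice = 1.0 if nd + nt == 0 else 2.0 * inter / (nd + nt)
    recall = 1.0 if nt == 0 else inter / nt
    precision = 1.0 if nd == 0 else inter / nd
    labels = measure.label(tru, connectivity=2)
    n_patches = int(labels.max())
    found = 0
    for lab in range(1, n_patches + 1):
        patch = labels == lab
        if np.sum(det & patch) >= 0.5 * patch.sum():
            found += 1
    return DetectionScore(dice=dice, recall=recall, precision=precision, n_true_found=found, n_true_patches=n_patches)
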