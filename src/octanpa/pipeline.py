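"""Five-step semiautomatic detection of capillary nonperfusion in en-face OCTA.

The method exploits the texture of the binarised angiogram: perfused retina is
a fine mixture of vessel and tissue pixels, so the windowed binary entropy of
the vessel image is high there; a nonperfused (ischemic) patch is locally
uniform and its entropy drops towards zero.  The stages are:

1.  **Low-pass background** — Gaussian smoothing (σ given in mm, converted via
    the pixel size) estimates the slowly varying illumination/contrast field.
2.  **High-pass correction** — raw − background removes the shading so one
    global threshold is meaningful across the whole widefield scan.
3.  **Binarisation** — normalise between the minimum and an upper percentile
    (default 95th) to [0, 1] and threshold above 0.5 → the *vessel image*.
4.  **Local entropy** — binary entropy H(p) of the vessel fraction p in a
    small sliding window (default 5 × 5 px, reflect padding), in bits.
5.  **Cluster extraction** — pixels with entropy below threshold (default
    0.3 bits), minus vessel and large-vessel pixels, grouped into connected
    components; only clusters strictly larger than a minimum physical area
    (default 0.09 mm²) are reported as ischemic.

Large vessels are wider than the entropy window and therefore *also* low
entropy; they are masked out via a morphological opening of the vessel image.

Everything is deterministic: identical inputs give bit-identical outputs, and
the result is invariant to affine rescaling of the raw intensities (a·v + b,
a > 0) because step 3 removes the affine scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import xlogy
from skimage import measure, morphology

from .errors import ContractError, DegenerateInputError, ParameterError
from .io import BinaryMask, EnFaceImage

__all__ = [
    "PipelineParams",
    "EntropyMap",
    "Cluster",
    "IschemiaResult",
    "binary_entropy",
    "lowpass_background",
    "highpass_correct",
    "binarize_vessels",
    "local_entropy",
    "large_vessel_mask",
    "ischemia_candidates",
    "label_candidates",
    "detect_ischemia",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineParams:
    """All algorithm constants, with the defaults of the five-step method.

    Attributes
    ----------
    sigma_mm
        Standard deviation of the Gaussian background estimate, in mm.  5 mm
        assumes any single ischemic region is smaller than ~5 × 5 mm.
    sigma_px
        Optional override in pixels (e.g. 350 to mimic a device-specific
        implementation); when set it takes precedence over ``sigma_mm``.
    norm_percentile
        Upper percentile used for intensity normalisation (linear
        interpolation between order statistics).
    vessel_threshold
        Cutoff on the normalised intensity above which a pixel is vessel.
    entropy_window_px
        Odd edge length of the square entropy window, in pixels.
    entropy_threshold_bits
        Pixels with windowed entropy strictly below this are ischemia
        candidates.
    min_cluster_area_mm2
        Clusters must strictly exceed this physical area to be reported.
    large_vessel_opening_radius_px
        Disk radius of the morphological opening that isolates large vessels;
        structures narrower than ~2·radius px are removed.
    connectivity
        4- or 8-neighbour connectivity for cluster labelling.
    """

    sigma_mm: float = 5.0
    sigma_px: float | None = None
    norm_percentile: float = 95.0
    vessel_threshold: float = 0.5
    entropy_window_px: int = 5
    entropy_threshold_bits: float = 0.3
    min_cluster_area_mm2: float = 0.09
    large_vessel_opening_radius_px: int = 3
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.sigma_mm > 0:
            raise ParameterError(f"sigma_mm must be > 0, got {self.sigma_mm}")
        if self.sigma_px is not None and not self.sigma_px > 0:
            raise ParameterError(f"sigma_px override must be > 0, got {self.sigma_px}")
        if not 0 < self.norm_percentile <= 100:
            raise ParameterError(f"norm_percentile must be in (0, 100], got {self.norm_percentile}")
        if not 0 < self.vessel_threshold < 1:
            raise ParameterError(f"vessel_threshold must be in (0, 1), got {self.vessel_threshold}")
        if self.entropy_window_px < 3 or self.entropy_window_px % 2 == 0:
            raise ParameterError(
                f"entropy_window_px must be odd and >= 3, got {self.entropy_window_px}"
            )
        if not 0 < self.entropy_threshold_bits < 1:
            raise ParameterError(
                f"entropy_threshold_bits must be in (0, 1), got {self.entropy_threshold_bits}"
            )
        if not self.min_cluster_area_mm2 > 0:
            raise ParameterError(
                f"min_cluster_area_mm2 must be > 0, got {self.min_cluster_area_mm2}"
            )
        if self.large_vessel_opening_radius_px < 1:
            raise ParameterError("large_vessel_opening_radius_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")

    def sigma_for(self, pixel_size_mm: float) -> float:
        """Effective Gaussian σ in pixels for a given pixel size."""
        return self.sigma_px if self.sigma_px is not None else self.sigma_mm / pixel_size_mm

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineParams":
        """Load parameters from a TOML file mirroring the field names."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class EntropyMap:
    """Per-pixel windowed binary entropy of the vessel image, in bits ∈ [0, 1]."""

    pixels: np.ndarray
    window_px: int
    pixel_size_mm: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.min() < 0 or px.max() > 1:
            raise ContractError("entropy values must lie in [0, 1] bits")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Cluster:
    """One connected ischemic region."""

    id: int
    pixel_count: int
    area_mm2: float
    centroid_rc: tuple[float, float]


@dataclass(frozen=True)
class IschemiaResult:
    """Labelled ischemic clusters plus summary metrics.

    ``label_raster`` holds 0 for perfused/excluded pixels and a dense cluster
    id k ≥ 1 otherwise; ids are assigned in decreasing area order (ties broken
    by the topmost-leftmost pixel).  ``candidate`` retains the pre-size-filter
    candidate mask so grader edits can be applied and re-filtered.
    """

    label_raster: np.ndarray
    clusters: tuple[Cluster, ...]
    total_area_mm2: float
    percent_of_scan: float
    params: PipelineParams
    pixel_size_mm: float
    candidate: BinaryMask | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def final_mask(self) -> BinaryMask:
        return BinaryMask(
            pixels=(self.label_raster > 0).astype(np.uint8),
            pixel_size_mm=self.pixel_size_mm,
            role="ischemia_final",
        )

    def summary(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "total_area_mm2": self.total_area_mm2,
            "percent_of_scan": self.percent_of_scan,
            "clusters": [
                {
                    "id": c.id,
                    "pixel_count": c.pixel_count,
                    "area_mm2": c.area_mm2,
                    "centroid_rc": list(c.centroid_rc),
                }
                for c in self.clusters
            ],
        }


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """H(p) = −p·log2 p − (1−p)·log2(1−p) in bits, with 0·log 0 ≡ 0."""
    p = np.asarray(p, dtype=np.float64)
    h = -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / math.log(2.0)
    # roundoff can leave tiny negatives at p ∈ {0, 1}
    return np.clip(h, 0.0, 1.0)


def lowpass_background(image: EnFaceImage, params: PipelineParams) -> EnFaceImage:
    """Step 1: Gaussian-smoothed background (reflect boundaries).

    Equals exact separable convolution with the sampled, normalised Gaussian
    kernel truncated at 4σ.
    """
    sigma = params.sigma_for(image.pixel_size_mm)
    if sigma < 1:
        raise ParameterError(
            f"Gaussian sigma is {sigma:.3g} px (< 1) at pixel size "
            f"{image.pixel_size_mm} mm — sigma_mm too small for this resolution"
        )
    smoothed = ndimage.gaussian_filter(image.pixels, sigma=sigma, mode="reflect", truncate=4.0)
    return image.with_pixels(smoothed)


def highpass_correct(image: EnFaceImage, background: EnFaceImage) -> EnFaceImage:
    """Step 2: subtract the background estimate; output may be negative."""
    if image.pixels.shape != background.pixels.shape:
        raise ContractError(
            f"shape mismatch: image {image.pixels.shape} vs background {background.pixels.shape}"
        )
    return image.with_pixels(image.pixels - background.pixels)


def binarize_vessels(image: EnFaceImage, params: PipelineParams) -> BinaryMask:
    """Step 3: percentile-normalise to [0, 1] and threshold → vessel image.

    v' = clip((v − min) / (p − min), 0, 1) with p the ``norm_percentile``-th
    percentile (linear interpolation); vessel ⇔ v' > ``vessel_threshold``.
    Values at or above the percentile saturate at 1 and are always vessel.
    """
    v = image.pixels
    vmin = float(v.min())
    p = float(np.percentile(v, params.norm_percentile))
    if p <= vmin:
        raise DegenerateInputError(
            "flat image: normalisation percentile equals the minimum — no dynamic range"
        )
    norm = np.clip((v - vmin) / (p - vmin), 0.0, 1.0)
    return BinaryMask(
        pixels=(norm > params.vessel_threshold).astype(np.uint8),
        pixel_size_mm=image.pixel_size_mm,
        role="vessel",
    )


def local_entropy(vessels: BinaryMask, params: PipelineParams) -> EntropyMap:
    """Step 4: windowed binary entropy of the vessel image.

    For each pixel, p is the vessel fraction in the centred
    ``entropy_window_px``² neighbourhood (reflect padding).  Vessel counts are
    accumulated as exact integers so H matches the closed form for every
    possible count.
    """
    if vessels.role != "vessel":
        raise ContractError(f"expected a mask with role 'vessel', got {vessels.role!r}")
    w = params.entropy_window_px
    counts = ndimage.correlate(
        vessels.pixels.astype(np.int64), np.ones((w, w), dtype=np.int64), mode="reflect"
    )
    h = binary_entropy(counts / float(w * w))
    return EntropyMap(pixels=h, window_px=w, pixel_size_mm=vessels.pixel_size_mm)


def large_vessel_mask(vessels: BinaryMask, params: PipelineParams) -> BinaryMask:
    """Isolate large vessels by morphological opening with a disk.

    Vessels wider than the entropy window are themselves low-entropy and must
    not be mistaken for nonperfusion; the opening (disk radius
    ``large_vessel_opening_radius_px``) keeps only structures wider than about
    twice the radius.  The result is a subset of the vessel mask.
    """
    if vessels.role != "vessel":
        raise ContractError(f"expected a mask with role 'vessel', got {vessels.role!r}")
    footprint = morphology.disk(params.large_vessel_opening_radius_px)
    opened = morphology.opening(vessels.astype_bool(), footprint)
    return BinaryMask(
        pixels=opened.astype(np.uint8), pixel_size_mm=vessels.pixel_size_mm, role="large_vessel"
    )


def ischemia_candidates(
    entropy: EntropyMap, vessels: BinaryMask, large: BinaryMask, params: PipelineParams
) -> BinaryMask:
    """Step 5a: low-entropy pixels that are neither vessel nor large vessel."""
    if not (entropy.shape == vessels.shape == large.shape):
        raise ContractError(
            f"shape mismatch: entropy {entropy.shape}, vessels {vessels.shape}, large {large.shape}"
        )
    cand = (
        (entropy.pixels < params.entropy_threshold_bits)
        & ~vessels.astype_bool()
        & ~large.astype_bool()
    )
    return BinaryMask(
        pixels=cand.astype(np.uint8),
        pixel_size_mm=entropy.pixel_size_mm,
        role="ischemia_candidate",
    )


def _exceeds_min_area(pixel_count: int, params: PipelineParams, pixel_size_mm: float) -> bool:
    # strict ">": a cluster exactly at the minimum area is rejected; the
    # isclose guard keeps float roundoff in count × px² from flipping ties
    area = pixel_count * pixel_size_mm**2
    if math.isclose(area, params.min_cluster_area_mm2, rel_tol=1e-9):
        return False
    return area > params.min_cluster_area_mm2


def label_candidates(candidate: BinaryMask, params: PipelineParams) -> IschemiaResult:
    """Step 5b: connected components + strict minimum-area filter + labelling.

    Kept clusters are relabelled 1..K in decreasing pixel-count order; equal
    areas are broken by ascending (row, column) of each cluster's
    topmost-leftmost pixel.
    """
    ps = candidate.pixel_size_mm
    skconn = 2 if params.connectivity == 8 else 1
    raw_labels = measure.label(candidate.astype_bool(), connectivity=skconn)
    n_raw = int(raw_labels.max())
    out = np.zeros_like(raw_labels, dtype=np.int32)
    clusters: list[Cluster] = []
    if n_raw:
        counts = np.bincount(raw_labels.ravel(), minlength=n_raw + 1)
        keep = [
            lab for lab in range(1, n_raw + 1) if _exceeds_min_area(int(counts[lab]), params, ps)
        ]
        # tie-break key: topmost-leftmost pixel in row-major order
        order_keys = {}
        if keep:
            rows, cols = np.nonzero(np.isin(raw_labels, keep))
            flat = rows.astype(np.int64) * raw_labels.shape[1] + cols
            for lab in keep:
                sel = raw_labels[rows, cols] == lab
                order_keys[lab] = int(flat[sel].min())
            keep.sort(key=lambda lab: (-counts[lab], order_keys[lab]))
            coms = ndimage.center_of_mass(
                np.ones_like(raw_labels), labels=raw_labels, index=keep
            )
            for new_id, (lab, com) in enumerate(zip(keep, coms), start=1):
                out[raw_labels == lab] = new_id
                clusters.append(
                    Cluster(
                        id=new_id,
                        pixel_count=int(counts[lab]),
                        area_mm2=int(counts[lab]) * ps**2,
                        centroid_rc=(float(com[0]), float(com[1])),
                    )
                )
    total = float(sum(c.area_mm2 for c in clusters))
    rows_, cols_ = candidate.shape
    percent = 100.0 * total / (rows_ * cols_ * ps**2)
    return IschemiaResult(
        label_raster=out,
        clusters=tuple(clusters),
        total_area_mm2=total,
        percent_of_scan=percent,
        params=params,
        pixel_size_mm=ps,
        candidate=candidate,
    )


def detect_ischemia(
    entropy: EntropyMap, vessels: BinaryMask, large: BinaryMask, params: PipelineParams
) -> IschemiaResult:
    """Step 5: candidates → connected components → strict area filter."""
    return label_candidates(ischemia_candidates(entropy, vessels, large, params), params)


def run_pipeline(
    image: EnFaceImage,
    params: PipelineParams | None = None,
    edits: Sequence[BinaryMask] | None = None,
    *,
    skip_highpass: bool = False,
) -> IschemiaResult:
    """Deterministic composition of the five steps (plus optional grader edits).

    ``edits`` are grader masks (roles ``grader_edit_add`` /
    ``grader_edit_remove``) applied in order to the candidate mask before the
    minimum-area filter runs, so the algorithm remains the final arbiter of
    cluster validity.  ``skip_highpass`` bypasses steps 1–2 and binarises the
    raw image directly (for ablation studies of the shading correction).
    """
    params = params or PipelineParams()
    if skip_highpass:
        corrected = image
    else:
        corrected = highpass_correct(image, lowpass_background(image, params))
    vessels = binarize_vessels(corrected, params)
    entropy = local_entropy(vessels, params)
    large = large_vessel_mask(vessels, params)
    candidate = ischemia_candidates(entropy, vessels, large, params)
    if edits:
        from .review import apply_grader_edits

        candidate = apply_grader_edits(candidate, edits)
    return label_candidates(candidate, params)
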