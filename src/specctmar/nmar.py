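"""Normalized metal artifact reduction (NMAR) applied per energy bin.

The corrupted samples are the sinogram entries whose rays intersect segmented
metal ("metal trace"). A piecewise-constant prior image (air / soft tissue /
bone, metal replaced by soft tissue) is forward projected; the measured
sinogram is divided by the prior sinogram, the trace is bridged by per-view
1-D linear interpolation in the flattened domain, and the result is
denormalized. Outside the trace the sinogram is returned bit-identical.

The metal mask is segmented once on the broad (summed-bin) image and the same
trace is applied to every bin, while priors are built per bin.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk, opening, remove_small_objects

from .physics import hu_to_mu, mu_to_hu
from .recon import BinImage, FanGeometry, fbp, project_image

__all__ = ["NmarParams", "segment_metal", "build_prior", "metal_trace",
           "nmar_correct", "reinsert_metal", "run_nmar_per_bin"]

PRIOR_EPS = 1e-6  # floor on the prior sinogram before division (air-only rays)


@dataclass(frozen=True)
class NmarParams:
    """Thresholds are in HU; the morphological kernel radius in pixels."""

    metal_hu: float = 3000.0
    air_hu: float = -300.0
    bone_hu: float = 300.0
    morph_radius: int = 3
    min_metal_pixels: int = 4
    prior_mode: str = "bone_preserving"


def segment_metal(hu_image: np.ndarray, threshold: float = 3000.0,
                  min_pixels: int = 4) -> np.ndarray:
    """Threshold metal in the image domain; small components are removed.

    Guards against implausible thresholds: a mask covering more than 20% of
    the non-air body is rejected.
    """
    hu_image = np.asarray(hu_image)
    if not np.all(np.isfinite(hu_image)):
        raise ValueError("image must be finite")
    mask = hu_image > threshold
    mask = remove_small_objects(mask, max_size=min_pixels - 1)
    body = hu_image > -500.0
    if body.any() and mask.sum() > 0.2 * body.sum():
        raise ValueError("metal mask covers >20% of the body; "
                         "threshold is implausibly low")
    return mask


def build_prior(hu_image: np.ndarray, thresholds: tuple = (-300.0, 300.0),
                morph_radius: int = 3,
                metal_mask: np.ndarray | None = None,
                mode: str = "bone_preserving") -> np.ndarray:
    """Segmentation prior (HU) with air / soft tissue / bone classes.

    Air and bone label maps are cleaned by morphological opening followed by
    closing with a disk kernel, suppressing boundary mis-segmentation (e.g.
    tooth edges) that would seed new streaks. Metal pixels take the
    soft-tissue value. Two prior flavors:

    * ``"bone_preserving"`` (default, the original NMAR choice): air and soft
      tissue are flattened to their class means while bone pixels keep their
      measured values - heterogeneous bone (jaw vs teeth) would otherwise
      inject more normalization error than the metal streaks it removes.
    * ``"three_level"``: bone is flattened to its class mean too, giving a
      strictly piecewise-constant prior with exactly three values.

    Returns the prior as an HU image.
    """
    air_hu, bone_hu = thresholds
    if air_hu >= bone_hu:
        raise ValueError("thresholds must be ordered (air_hu < bone_hu)")
    if mode not in ("bone_preserving", "three_level"):
        raise ValueError(f"unknown prior mode {mode!r}")
    hu = np.asarray(hu_image, dtype=float)
    metal = (np.zeros(hu.shape, bool) if metal_mask is None
             else np.asarray(metal_mask, bool))
    air = hu < air_hu
    bone = (hu >= bone_hu) & ~metal
    if morph_radius > 0:
        selem = disk(morph_radius)
        air = closing(opening(air, selem), selem)
        bone = closing(opening(bone, selem), selem)
        bone &= ~metal
        air &= ~bone
    soft = ~(air | bone)

    prior = np.empty_like(hu)
    soft_clean = soft & ~metal
    soft_val = float(hu[soft_clean].mean()) if soft_clean.any() else 0.0
    air_val = float(hu[air].mean()) if air.any() else -1000.0
    prior[air] = air_val
    prior[soft] = soft_val
    if mode == "three_level":
        bone_val = float(hu[bone].mean()) if bone.any() else soft_val
        prior[bone] = bone_val
    else:
        prior[bone] = hu[bone]
    prior[metal] = soft_val
    return prior


def metal_trace(mask: np.ndarray, geometry: FanGeometry,
                pixel_size: float) -> np.ndarray:
    """Boolean sinogram of rays intersecting the metal mask."""
    sino = project_image(mask.astype(np.float64), geometry, pixel_size)
    return sino > 0.5 * pixel_size


def nmar_correct(p: np.ndarray, prior_sino: np.ndarray,
                 trace: np.ndarray) -> np.ndarray:
    """Inpaint the metal trace of ``p`` in the prior-normalized domain.

    ``prior_sino`` must be the forward projection of the prior image in the
    same units as ``p``. Outside the trace the output equals ``p`` exactly.
    """
    if p.shape != prior_sino.shape or p.shape != trace.shape:
        raise ValueError("sinogram shapes do not match")
    if not trace.any():
        return p.copy()
    norm = np.maximum(prior_sino, PRIOR_EPS)
    pn = p / norm
    out = p.copy()
    idx = np.arange(p.shape[1])
    for v in range(p.shape[0]):
        row_trace = trace[v]
        if not row_trace.any():
            continue
        keep = ~row_trace
        if keep.sum() < 2:
            warnings.warn("metal trace covers an entire view; "
                          "falling back to the prior", stacklevel=2)
            out[v, row_trace] = prior_sino[v, row_trace]
            continue
        filled = np.interp(idx[row_trace], idx[keep], pn[v, keep])
        out[v, row_trace] = filled * norm[v, row_trace]
    return out


def reinsert_metal(image: BinImage, mask: np.ndarray,
                   metal_mu: float) -> BinImage:
    """Set masked pixels to ``metal_mu``, leaving all others untouched."""
    if image.mu.shape != mask.shape:
        raise ValueError("shapes do not match")
    mu = image.mu.copy()
    mu[np.asarray(mask, bool)] = metal_mu
    return BinImage(mu, image.bin_index, image.pixel_size)


def run_nmar_per_bin(bin_ps: list[np.ndarray], bin_images: list[BinImage],
                     broad_hu: np.ndarray, mu_water: list[float],
                     geometry: FanGeometry,
                     params: NmarParams = NmarParams(),
                     filter_name: str = "hann") -> tuple[list[BinImage], np.ndarray]:
    """Correct every bin with a common metal trace and per-bin priors.

    Parameters
    ----------
    bin_ps : per-bin line-integral sinograms.
    bin_images : matching uncorrected reconstructions (mu, 1/mm).
    broad_hu : summed-bin HU image used for metal segmentation.
    mu_water : per-bin effective water attenuation (for HU conversion).

    Returns the corrected, re-reconstructed bin images and the metal mask.
    """
    if len(bin_ps) != len(bin_images):
        raise ValueError("sinogram/image count mismatch")
    mask = segment_metal(broad_hu, params.metal_hu, params.min_metal_pixels)
    n = bin_images[0].mu.shape[0]
    pixel_size = bin_images[0].pixel_size
    if not mask.any():
        return [BinImage(im.mu.copy(), im.bin_index, im.pixel_size)
                for im in bin_images], mask
    trace = metal_trace(mask, geometry, pixel_size)
    corrected = []
    for p, im, mw in zip(bin_ps, bin_images, mu_water):
        hu = mu_to_hu(im.mu, mw)
        prior_hu = build_prior(hu, (params.air_hu, params.bone_hu),
                               params.morph_radius, metal_mask=mask,
                               mode=params.prior_mode)
        prior_mu = np.clip(hu_to_mu(prior_hu, mw), 0.0, None)
        prior_sino = project_image(prior_mu, geometry, pixel_size)
        p_corr = nmar_correct(p, prior_sino, trace)
        corrected.append(BinImage(fbp(p_corr, geometry, pixel_size, n,
                                      filter_name), im.bin_index, pixel_size))
    return corrected, mask
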