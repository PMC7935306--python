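"""ROI statistics, CNR, uniformity, iodine-recovery fits, artifact RMSE.

The CNR convention follows the lesion/tissue/air ROI scheme: ROI1 covers the
iodine-enhanced lesion, three ROI2s sample normal tissue away from streaks,
three ROI3s sample surrounding air. Background noise is the arithmetic mean of
the three ROI3 standard deviations and ``CNR_k = (mean_1 - mean_2k) / noise``.
The summary is the mean and sample SD of the three CNRs after rounding each to
the 0.1 reporting precision, matching summaries that are derived from CNRs
printed at one decimal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RoiSpec", "CnrReport", "roi_mask", "roi_stats", "compute_cnr",
           "cnr_from_stats", "uniformity", "linear_fit_r2", "artifact_rmse"]


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: center (x, y) in mm (isocenter origin) and radius in mm."""

    name: str
    center: tuple
    radius: float = 5.0


def roi_mask(shape: tuple, pixel_size: float, roi: RoiSpec) -> np.ndarray:
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size
    y = ((ny - 1) / 2.0 - np.arange(ny)) * pixel_size
    xx, yy = np.meshgrid(x, y)
    r2 = (xx - roi.center[0]) ** 2 + (yy - roi.center[1]) ** 2
    mask = r2 <= roi.radius ** 2
    edge = (abs(roi.center[0]) + roi.radius > abs(x).max() + pixel_size / 2 or
            abs(roi.center[1]) + roi.radius > abs(y).max() + pixel_size / 2)
    if edge:
        raise ValueError(f"ROI {roi.name} extends outside the image")
    return mask


def roi_stats(image: np.ndarray, rois: list[RoiSpec],
              pixel_size: float) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of the image inside each circular ROI."""
    rows = []
    for roi in rois:
        mask = roi_mask(image.shape, pixel_size, roi)
        if mask.sum() < 20:
            raise ValueError(f"ROI {roi.name} holds fewer than 20 pixels")
        vals = image[mask]
        rows.append({"roi": roi.name, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)), "n_pixels": int(mask.sum())})
    return pd.DataFrame(rows).set_index("roi")


@dataclass(frozen=True)
class CnrReport:
    cnr: tuple            # (CNR1, CNR2, CNR3)
    noise: float          # mean of the three air-ROI SDs (HU)
    summary_mean: float
    summary_sd: float


def compute_cnr(roi1_mean: float, roi2_means, roi3_sds,
                round_decimals: int = 1) -> CnrReport:
    """CNRs of the lesion against each tissue ROI, plus their summary.

    ``noise`` is the arithmetic mean of the three air-ROI SDs. The summary
    mean/SD are computed over the CNRs rounded to ``round_decimals`` (the
    published reporting precision); pass ``None`` to summarize unrounded.
    """
    roi2_means = list(roi2_means)
    roi3_sds = list(roi3_sds)
    if len(roi2_means) != 3 or len(roi3_sds) != 3:
        raise ValueError("need three tissue ROIs and three air ROIs")
    noise = float(np.mean(roi3_sds))
    if noise <= 0:
        raise ValueError("background noise must be positive")
    cnrs = tuple((roi1_mean - m2) / noise for m2 in roi2_means)
    summ = (np.round(cnrs, round_decimals) if round_decimals is not None
            else np.asarray(cnrs))
    return CnrReport(cnrs, noise, float(summ.mean()),
                     float(summ.std(ddof=1)))


def cnr_from_stats(stats_df: pd.DataFrame, roi1: str = "ROI1",
                   roi2_prefix: str = "ROI2", roi3_prefix: str = "ROI3",
                   ) -> CnrReport:
    """Convenience wrapper reading the ROI naming scheme from a stats table."""
    roi2 = sorted(n for n in stats_df.index if n.startswith(roi2_prefix))
    roi3 = sorted(n for n in stats_df.index if n.startswith(roi3_prefix))
    return compute_cnr(stats_df.loc[roi1, "mean"],
                       [stats_df.loc[n, "mean"] for n in roi2],
                       [stats_df.loc[n, "sd"] for n in roi3])


def uniformity(image: np.ndarray, center_roi: RoiSpec,
               periphery_rois: list[RoiSpec], pixel_size: float) -> float:
    """Max absolute difference between the center and peripheral ROI means (HU)."""
    stats_df = roi_stats(image, [center_roi] + list(periphery_rois), pixel_size)
    center = stats_df.loc[center_roi.name, "mean"]
    periph = stats_df.drop(center_roi.name)["mean"]
    return float(np.abs(periph - center).max())


def linear_fit_r2(measured, truth):
    """OLS fit of measured vs true concentration.

    Returns ``(slope, intercept, r2, per_point_abs_error)``.
    """
    measured = np.asarray(measured, float)
    truth = np.asarray(truth, float)
    if measured.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(truth) == 0:
        raise ValueError("degenerate truth values")
    res = stats.linregress(truth, measured)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), np.abs(measured - truth))


def artifact_rmse(image: np.ndarray, reference: np.ndarray,
                  exclude_mask: np.ndarray | None = None) -> float:
    """Root-mean-square difference (image units) outside ``exclude_mask``."""
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    if image.shape != reference.shape:
        raise ValueError("shapes do not match")
    keep = (np.ones(image.shape, bool) if exclude_mask is None
            else ~np.asarray(exclude_mask, bool))
    diff = image[keep] - reference[keep]
    return float(np.sqrt(np.mean(diff ** 2)))
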