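"""Image quantifications: membrane/total intensity ratio and Pearson colocalization.

The membrane-enrichment measure is the ratio of the background-subtracted
mean intensity over membrane ROIs to the background-subtracted mean over the
whole-cell ROI. Colocalization between two channels is quantified by the
Pearson correlation of pixel intensities over a mask, either plain or after
a Costes-style automatic threshold search (the largest joint thresholds for
which the sub-threshold pixels are uncorrelated; the coefficient is then
computed over pixels above threshold in either channel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROISet", "RatioResult", "ColocResult", "membrane_total_ratio", "pearson_colocalization"]


@dataclass(frozen=True)
class ROISet:
    """Boolean pixel masks for ratio quantification.

    ``membrane_rois`` is a list of masks on the cell membrane, ``total_roi``
    covers the whole cell and ``background_roi`` an empty area of the image;
    the background must be disjoint from the cell.
    """

    membrane_rois: list[np.ndarray]
    total_roi: np.ndarray
    background_roi: np.ndarray

    def __post_init__(self) -> None:
        if not self.membrane_rois:
            raise ValueError("need at least one membrane ROI")
        shape = self.total_roi.shape
        masks = [*self.membrane_rois, self.total_roi, self.background_roi]
        for m in masks:
            if m.shape != shape:
                raise ValueError("all ROI masks must share the image shape")
            if m.dtype != bool:
                raise ValueError("ROI masks must be boolean arrays")
            if not m.any():
                raise ValueError("ROI masks must be non-empty")
        if np.any(self.total_roi & self.background_roi):
            raise ValueError("background ROI must be disjoint from the cell ROI")


@dataclass(frozen=True)
class RatioResult:
    """Membrane/total ratio and the three background-corrected means behind it."""

    membrane_mean: float
    total_mean: float
    background_mean: float
    ratio: float


@dataclass(frozen=True)
class ColocResult:
    """Pearson colocalization coefficient over a pixel mask."""

    pearson_r: float
    thresholds: tuple[float, float] | None
    n_pixels: int


def membrane_total_ratio(image: np.ndarray, rois: ROISet) -> RatioResult:
    """Background-subtracted membrane/total mean-intensity ratio.

    Membrane pixels are pooled across all membrane ROIs; the ratio is
    (<membrane> - <background>) / (<total> - <background>).
    """
    image = np.asarray(image, dtype=float)
    membrane = np.zeros(image.shape, dtype=bool)
    for m in rois.membrane_rois:
        membrane |= m
    m_mean = float(image[membrane].mean())
    t_mean = float(image[rois.total_roi].mean())
    b_mean = float(image[rois.background_roi].mean())
    if t_mean <= b_mean:
        raise ValueError(
            f"total-cell mean ({t_mean:g}) does not exceed background ({b_mean:g})"
        )
    return RatioResult(
        membrane_mean=m_mean,
        total_mean=t_mean,
        background_mean=b_mean,
        ratio=(m_mean - b_mean) / (t_mean - b_mean),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson coefficient undefined for a constant channel")
    return float(stats.pearsonr(x, y).statistic)


def _costes_thresholds(x: np.ndarray, y: np.ndarray, n_steps: int = 200):
    """Largest joint thresholds whose sub-threshold pixels have r <= 0.

    Thresholds descend along the orthogonal regression line y = a*x + b,
    following the Costes procedure.
    """
    a, b = np.polyfit(x, y, 1)
    if a <= 0:
        return float(x.min()), float(y.min())
    for t1 in np.linspace(x.max(), x.min(), n_steps):
        t2 = a * t1 + b
        below = (x < t1) & (y < t2)
        xb, yb = x[below], y[below]
        if xb.size < 2 or np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        if _pearson(xb, yb) <= 0:
            return float(t1), float(t2)
    return float(x.min()), float(y.min())


def pearson_colocalization(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray,
    mode: str = "plain",
) -> ColocResult:
    """Pearson colocalization of two channels over a mask.

    ``mode="plain"`` correlates all masked pixels; ``mode="auto_threshold"``
    first finds Costes thresholds and correlates only pixels above threshold
    in either channel.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape or ch1.shape != mask.shape:
        raise ValueError("channels and mask must share one shape")
    if not mask.any():
        raise ValueError("mask is empty")
    x = ch1[mask]
    y = ch2[mask]
    if mode == "plain":
        return ColocResult(pearson_r=_pearson(x, y), thresholds=None, n_pixels=x.size)
    if mode == "auto_threshold":
        t1, t2 = _costes_thresholds(x, y)
        keep = (x >= t1) | (y >= t2)
        return ColocResult(
            pearson_r=_pearson(x[keep], y[keep]),
            thresholds=(t1, t2),
            n_pixels=int(keep.sum()),
        )
    raise ValueError(f"unknown mode {mode!r}")
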