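"""Stain separation, in-ROI Otsu thresholding, and area-ratio PI estimation.

RGB pixels are unmixed into hematoxylin / eosin / DAB optical densities by
color deconvolution with the standard published stain matrix.  Within the
detected ROI each stain channel is thresholded — by Otsu's criterion on that
slide, or by reference thresholds averaged over training slides ("biasing"),
which protects slides whose own histogram misleads Otsu.  After per-channel
binary closing and dilation the proliferation index is approximated as

    PI = area(DAB mask) / area(DAB mask ∪ hematoxylin mask)

i.e. brown-stained nuclear area over all relevant nuclear area.  No attempt
is made to split touching nuclei; the area ratio replaces counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.color import rgb2hed
from skimage.filters import threshold_otsu
from skimage.morphology import closing as binary_closing
from skimage.morphology import dilation as binary_dilation
from skimage.morphology import disk

from ki67pi.io_annotations import SlideImage
from ki67pi.roi import ROIMask

logger = logging.getLogger(__name__)

#: Minimum separation (normalized optical density) between the sub- and
#: supra-threshold means for a channel to count as genuinely bimodal.  When a
#: stain is absent the channel holds only background noise, and Otsu's cut
#: would promote half of that noise to "stained"; below this separation the
#: channel mask is treated as empty.
MIN_MODE_SEPARATION = 0.015


class SegmentationError(ValueError):
    """Raised when segmentation cannot produce a defined PI."""


@dataclass(frozen=True)
class StainThresholds:
    """Optical-density cuts for the DAB and hematoxylin channels."""

    t_dab: float
    t_hema: float
    provenance: str = "otsu"  # otsu | biased | reference

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_dab) and np.isfinite(self.t_hema)):
            raise ValueError("thresholds must be finite")


@dataclass
class PIEstimate:
    """An area-ratio proliferation index with provenance flags."""

    slide_id: str
    pi: float
    dab_area: int
    relevant_area: int
    roi_fallback: bool
    method: str  # base | roi | roi_bias
    thresholds: StainThresholds | None = None

    def to_dict(self) -> dict:
        d = {
            "slide_id": self.slide_id,
            "method": self.method,
            "pi": self.pi,
            "dab_area": self.dab_area,
            "relevant_area": self.relevant_area,
            "roi_fallback": self.roi_fallback,
        }
        if self.thresholds is not None:
            d["thresholds"] = {
                "t_dab": self.thresholds.t_dab,
                "t_hema": self.thresholds.t_hema,
                "provenance": self.thresholds.provenance,
            }
        return d


def rgb_to_hed(image: SlideImage | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (dab_density, hema_density) by HED color deconvolution.

    Densities are clipped at 0; the eosin channel is discarded (Ki-67 IHC
    slides carry no eosin).
    """
    pixels = image.pixels if isinstance(image, SlideImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) raster, got shape {pixels.shape}")
    hed = rgb2hed(pixels)
    hema = np.clip(hed[:, :, 0], 0.0, None)
    dab = np.clip(hed[:, :, 2], 0.0, None)
    return dab, hema


def otsu_in_mask(channel: np.ndarray, mask: ROIMask | np.ndarray) -> float:
    """Otsu threshold of a density channel restricted to a pixel mask.

    Maximizes between-class variance on a 256-bin histogram of the masked
    pixels' observed range.  Restricting the histogram to the ROI keeps
    staining artifacts outside it from biasing the intensity distribution.
    """
    mask_arr = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != channel.shape:
        raise ValueError("channel and mask shapes differ")
    values = channel[mask_arr]
    if values.size == 0:
        raise SegmentationError("empty mask: apply the whole-image fallback first")
    if np.ptp(values) == 0:
        raise SegmentationError("degenerate histogram: channel constant within mask")
    return float(threshold_otsu(values, nbins=256))


def _channel_mask(
    channel: np.ndarray,
    region: np.ndarray,
    threshold: float | None,
    min_mode_separation: float,
) -> tuple[np.ndarray, float]:
    """Binary stained-pixel mask for one channel inside ``region``.

    With ``threshold=None`` the cut is Otsu-in-region, guarded by the mode
    separation check for effectively unstained channels.
    """
    if threshold is None:
        t = otsu_in_mask(channel, region)
        values = channel[region]
        above = values > t
        if above.any() and (~above).any():
            separation = float(values[above].mean() - values[~above].mean())
        else:
            separation = 0.0
        if separation < min_mode_separation:
            logger.info(
                "channel mode separation %.3f below %.3f: treating as unstained",
                separation,
                min_mode_separation,
            )
            return np.zeros_like(region), t
    else:
        t = threshold
    return (channel > t) & region, t


def reference_thresholds(
    slides: Sequence[tuple[SlideImage, ROIMask]],
    min_mode_separation: float = MIN_MODE_SEPARATION,
) -> StainThresholds:
    """Average per-slide Otsu thresholds inside ground-truth ROIs.

    For every training slide the DAB and hematoxylin thresholds are computed
    by Otsu within that slide's expert-derived ROI; the arithmetic mean per
    channel becomes the reference used to bias held-out slides.  Slides whose
    ROI is empty, or whose channel lacks a bimodal histogram, are skipped
    with a warning for that channel.
    """
    if not slides:
        raise ValueError("at least one training slide is required")
    dab_ts: list[float] = []
    hema_ts: list[float] = []
    for image, roi in slides:
        if roi.empty:
            logger.warning("slide %s: empty ground-truth ROI, skipped", image.slide_id)
            continue
        dab, hema = rgb_to_hed(image)
        for channel, sink in ((dab, dab_ts), (hema, hema_ts)):
            try:
                t = otsu_in_mask(channel, roi)
            except SegmentationError:
                logger.warning("slide %s: degenerate channel, skipped", image.slide_id)
                continue
            values = channel[roi.mask]
            above = values > t
            if not above.any() or not (~above).any():
                continue
            if values[above].mean() - values[~above].mean() < min_mode_separation:
                logger.warning(
                    "slide %s: channel effectively unstained, excluded from reference",
                    image.slide_id,
                )
                continue
            sink.append(t)
    if not dab_ts or not hema_ts:
        raise SegmentationError("no usable training slides for reference thresholds")
    return StainThresholds(
        t_dab=float(np.mean(dab_ts)), t_hema=float(np.mean(hema_ts)), provenance="reference"
    )


def combine_thresholds(
    own: StainThresholds, reference: StainThresholds, weight: float = 1.0
) -> StainThresholds:
    """Convex combination ``weight * reference + (1 - weight) * own``.

    The default weight 1.0 replaces the slide's own Otsu thresholds with the
    reference average outright — reference thresholds exist precisely for
    slides where per-image Otsu fails; blending is available for softer bias.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {weight}")
    return StainThresholds(
        t_dab=weight * reference.t_dab + (1 - weight) * own.t_dab,
        t_hema=weight * reference.t_hema + (1 - weight) * own.t_hema,
        provenance="biased",
    )


def segment_and_estimate(
    image: SlideImage,
    roi: ROIMask | None,
    thresholds: StainThresholds | None = None,
    closing_radius: int = 1,
    dilation_radius: int = 1,
    method: str = "roi",
    min_mode_separation: float = MIN_MODE_SEPARATION,
) -> PIEstimate:
    """Segment stained nuclei within the ROI and estimate PI as an area ratio.

    ``roi=None`` (the "base" method) or an empty ROI triggers the fallback:
    segmentation runs on the whole image and the estimate is flagged with
    ``roi_fallback`` when the ROI stage produced an empty mask.  Explicit
    ``thresholds`` (reference or biased) override per-slide Otsu.  Each
    channel mask is binary-closed then dilated with disk structuring
    elements before the masks are combined.
    """
    H, W = image.height, image.width
    roi_fallback = False
    if roi is None:
        region = np.ones((H, W), dtype=bool)
    elif roi.mask.shape != (H, W):
        raise ValueError("ROI mask size differs from image size")
    elif roi.empty:
        roi_fallback = True
        region = np.ones((H, W), dtype=bool)
    else:
        region = roi.mask

    dab, hema = rgb_to_hed(image)
    dab_mask, t_dab = _channel_mask(
        dab, region, thresholds.t_dab if thresholds else None, min_mode_separation
    )
    hema_mask, t_hema = _channel_mask(
        hema, region, thresholds.t_hema if thresholds else None, min_mode_separation
    )

    for radius, op in ((closing_radius, binary_closing), (dilation_radius, binary_dilation)):
        if radius > 0:
            footprint = disk(radius)
            dab_mask = op(dab_mask, footprint)
            hema_mask = op(hema_mask, footprint)

    relevant_mask = dab_mask | hema_mask
    relevant_area = int(relevant_mask.sum())
    if relevant_area == 0:
        raise SegmentationError(f"slide {image.slide_id!r}: no cells segmented")
    dab_area = int(dab_mask.sum())

    used = thresholds if thresholds is not None else StainThresholds(
        t_dab=t_dab, t_hema=t_hema, provenance="otsu"
    )
    return PIEstimate(
        slide_id=image.slide_id,
        pi=dab_area / relevant_area,
        dab_area=dab_area,
        relevant_area=relevant_area,
        roi_fallback=roi_fallback,
        method=method,
        thresholds=used,
    )


def overlay_segmentation(
    image: SlideImage,
    dab_mask: np.ndarray,
    hema_mask: np.ndarray,
) -> np.ndarray:
    """Report overlay: immunopositive outlines in red, immunonegative in green."""
    from skimage.segmentation import find_boundaries

    out = image.pixels.copy()
    out[find_boundaries(dab_mask, mode="outer")] = (220, 30, 30)
    out[find_boundaries(hema_mask & ~dab_mask, mode="outer")] = (30, 180, 30)
    return out
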