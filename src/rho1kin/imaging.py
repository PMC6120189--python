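"""Membrane-fluorescence quantification: automatic ROI placement from a cell
marker channel, background-corrected membrane intensity (delta-ROI =
membrane mean - background mean), and normalization of condition means to a
reference condition.

The published procedure drew the cell-surface ROI by hand in the marker
(eGFP) channel and transferred it to the receptor-label channel; here the
ROIs are placed deterministically: threshold the median-filtered marker
channel, keep the largest connected component as the cell, take a boundary
band just inside its edge as the membrane ROI, and use pixels far from any
cell as the background ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from skimage.measure import label as cc_label


class ImagingError(ValueError):
    """Quantification failure (blank image, empty or overlapping ROIs)."""


@dataclass
class ROIQuant:
    """Background-corrected membrane fluorescence for one image."""

    roi_cs_mean: float  # mean label intensity over the membrane (cell-surface) ROI
    roi_b_mean: float  # mean label intensity over the background ROI
    delta_roi: float  # roi_cs_mean - roi_b_mean, exactly
    image_id: str = ""
    n_membrane_px: int = 0
    n_background_px: int = 0


def marker_mask(
    marker_channel: np.ndarray,
    threshold_frac: float = 0.5,
    band_width: int = 4,
    background_margin: int = 10,
    median_size: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment the cell from the marker channel and derive the two ROIs.

    Returns ``(cell_mask, membrane_roi, background_roi)``.  The threshold is
    ``threshold_frac`` times the maximum of a median-filtered copy; the cell
    is the largest connected component above it; the membrane ROI is the
    band of ``band_width`` pixels just inside the cell edge; the background
    ROI is every pixel farther than ``background_margin`` pixels from any
    above-threshold component.
    """
    img = np.asarray(marker_channel, dtype=float)
    if img.ndim != 2:
        raise ImagingError(f"marker channel must be 2-D, got shape {img.shape}")
    smooth = ndimage.median_filter(img, size=median_size)
    threshold = threshold_frac * smooth.max()
    above = smooth > threshold
    if not above.any():
        raise ImagingError("no pixels above threshold; cannot find a cell")
    labels = cc_label(above, connectivity=1)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    cell = labels == int(np.argmax(sizes))
    eroded = ndimage.binary_erosion(cell, iterations=band_width)
    membrane = cell & ~eroded
    near_any_cell = ndimage.binary_dilation(above, iterations=background_margin)
    background = ~near_any_cell
    if not background.any():
        raise ImagingError("no background pixels beyond the margin")
    return cell, membrane, background


def quantify_droi(
    label_channel: np.ndarray,
    membrane_roi: np.ndarray,
    background_roi: np.ndarray,
    image_id: str = "",
) -> ROIQuant:
    """Mean label intensity over the two ROIs and their difference (delta-ROI)."""
    label_channel = np.asarray(label_channel, dtype=float)
    membrane_roi = np.asarray(membrane_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if not membrane_roi.any() or not background_roi.any():
        raise ImagingError("ROIs must be non-empty")
    if (membrane_roi & background_roi).any():
        raise ImagingError("membrane and background ROIs overlap")
    cs = float(label_channel[membrane_roi].mean())
    b = float(label_channel[background_roi].mean())
    return ROIQuant(
        roi_cs_mean=cs,
        roi_b_mean=b,
        delta_roi=cs - b,
        image_id=image_id,
        n_membrane_px=int(membrane_roi.sum()),
        n_background_px=int(background_roi.sum()),
    )


def normalize_to_reference(
    values: dict[str, list[float]], reference: str
) -> dict[str, dict]:
    """Express per-condition delta-ROI means as percent of a reference condition.

    Returns, per condition, the raw values, the condition mean, and the mean
    as a percentage of the reference condition mean.
    """
    if reference not in values or len(values[reference]) == 0:
        raise ImagingError(f"reference condition {reference!r} has no values")
    ref_mean = float(np.mean(values[reference]))
    if ref_mean <= 0:
        raise ImagingError(f"reference mean must be > 0, got {ref_mean}")
    out: dict[str, dict] = {}
    for condition, vals in values.items():
        vals = [float(v) for v in vals]
        if not vals:
            raise ImagingError(f"condition {condition!r} has no values")
        mean = float(np.mean(vals))
        out[condition] = {
            "values": vals,
            "mean": mean,
            "percent_of_reference": 100.0 * mean / ref_mean,
        }
    return out
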