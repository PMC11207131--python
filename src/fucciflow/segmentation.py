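"""Classical per-frame nuclear segmentation and detection measurement.

The baseline pipeline is smooth -> threshold (Otsu or fixed) -> fill holes ->
optional distance-transform watershed split of touching nuclei -> small-object
removal. It is a self-contained stand-in for an external deep-learning
segmenter; label stacks produced elsewhere can be loaded with
:func:`load_external_masks` and passed down the pipeline unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure, segmentation as sk_seg
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .config import SegmentationParams
from .core import Channel, Detection


def segment_frame(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Segment one intensity frame into a positive-integer label mask.

    A constant frame under Otsu yields an empty mask (no threshold exists),
    not an exception.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("segment_frame expects a 2-D image")
    if not np.all(np.isfinite(image)) or image.min() < 0:
        raise ValueError("image must be finite and non-negative")

    smoothed = (ndi.gaussian_filter(image, params.smoothing_sigma_px)
                if params.smoothing_sigma_px > 0 else image)

    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return np.zeros(image.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    mask = smoothed > thr
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)

    if params.split_touching:
        distance = ndi.distance_transform_edt(mask)
        coords = peak_local_max(distance, min_distance=params.watershed_min_distance_px,
                                labels=mask, exclude_border=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = measure.label(mask)
        else:
            labels = sk_seg.watershed(-distance, markers, mask=mask)
    else:
        labels = measure.label(mask)

    # drop components smaller than min_area_px2 (strictly)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < params.min_area_px2)
    if small.size:
        labels[np.isin(labels, small)] = 0
    # relabel sequentially so label ids are dense and deterministic
    labels, _, _ = sk_seg.relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_stack(stack: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Apply :func:`segment_frame` to every page of a T x H x W stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("segment_stack expects a T x H x W stack")
    return np.stack([segment_frame(frame, params) for frame in stack])


def _label_contour(region_mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray | None:
    """Sub-pixel 0.5-level contour of one label, as (x, y) vertices."""
    padded = np.pad(region_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    c = max(contours, key=len)  # (row, col) in padded coords
    rows = c[:, 0] - 1 + offset[0]
    cols = c[:, 1] - 1 + offset[1]
    return np.column_stack([cols, rows])  # (x, y)


def _polygon_length(poly: np.ndarray) -> float:
    d = np.diff(poly, axis=0)
    return float(np.sqrt((d ** 2).sum(axis=1)).sum())


def extract_detections(labels: np.ndarray, intensity: np.ndarray,
                       frame: int, channel: Channel) -> list[Detection]:
    """Measure one Detection per label: unweighted centroid, pixel-count
    area, 0.5-level polygonal contour and its length, mean intensity."""
    labels = np.asarray(labels)
    intensity = np.asarray(intensity)
    if labels.shape != intensity.shape:
        raise ValueError("label mask and intensity image shapes differ")
    detections = []
    for region in measure.regionprops(labels, intensity_image=intensity):
        r0, c0, _, _ = region.bbox
        contour = _label_contour(region.image, (r0, c0))
        perimeter = _polygon_length(contour) if contour is not None else 0.0
        cy, cx = region.centroid
        detections.append(Detection(
            frame=frame, channel=channel, label_id=int(region.label),
            x=float(cx), y=float(cy), area=float(region.area),
            perimeter=perimeter,
            mean_intensity=float(region.intensity_mean),
            contour=contour))
    return detections


def detect_stack(stack: np.ndarray, label_stack: np.ndarray,
                 channel: Channel) -> list[Detection]:
    """Measure detections for every frame of a segmented stack."""
    if stack.shape != label_stack.shape:
        raise ValueError("intensity and label stacks must share shape")
    out: list[Detection] = []
    for t in range(stack.shape[0]):
        out.extend(extract_detections(label_stack[t], stack[t], t, channel))
    return out


def load_external_masks(path: str | Path,
                        expected_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Load a multi-page integer label TIFF produced by an external segmenter.

    Labels are passed through verbatim (never renumbered). When
    ``expected_shape`` is given the stack must match it exactly.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a T x H x W label stack, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label stack must be integer-typed, got {arr.dtype}")
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(f"label stack shape {arr.shape} does not match the "
                         f"paired intensity stack {tuple(expected_shape)}")
    return arr.astype(np.int32)
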