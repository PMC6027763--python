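"""The automated measurement procedure: raw channels to percent immunoreactive area.

The canonical stage order for a tau marker is

    project -> correct_background -> autofluorescence_mask -> subtract_mask
            -> edge_enhance -> detect_objects -> measure_ir_area

i.e. z-planes are max-projected, a Gaussian lowpass estimate of the
background is subtracted, objects found by thresholding the unlabeled
autofluorescence channel are masked out of the marker channel (lipofuscin
and other autofluorescent material appear in every channel and would
otherwise be counted as signal), a high-boost edge filter sharpens object
borders to make thresholding robust, and connected components passing size
and shape restrictions are summed into a percent-of-imaged-area value.
Object intensities are always reported from the raw, pre-enhancement image.

Plaque cores in the ThioflavinS channel take a shorter route: plain
thresholding plus a minimum-size restriction.  Tangles are only weakly
ThioS-positive and small, so the brightness gap and the size cutoff together
leave only plaque cores.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .types import (
    ChannelImage,
    DetectedObject,
    ImageStack,
    MeasurementRecord,
    SegmentationParams,
    ThresholdSpec,
)

logger = logging.getLogger(__name__)


def project_stack(stack: ImageStack) -> ChannelImage:
    """Maximum-intensity projection of a z-stack to a single 2-D image."""
    planes = stack.planes
    if len(planes) == 1:
        return planes[0]
    out = np.maximum.reduce([p.pixels for p in planes])
    return planes[0].with_pixels(out)


def correct_background(img: ChannelImage, background_sigma_um: float) -> ChannelImage:
    """Subtract a Gaussian lowpass estimate of the background, clipping at 0.

    ``background_sigma_um`` should be well above the diameter of the largest
    object of interest (roughly 5x is a good rule) so the lowpass tracks
    illumination and diffuse background rather than the objects themselves.
    A constant image maps to the zero image exactly.
    """
    if not background_sigma_um > 0:
        raise ValueError("background_sigma_um must be > 0")
    sigma_px = background_sigma_um / img.pixel_size_um
    lowpass = _gaussian_lowpass(img.pixels, sigma_px)
    return img.with_pixels(np.clip(img.pixels - lowpass, 0, None))


def _gaussian_lowpass(pixels: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian lowpass; at large sigma the (smooth) estimate is computed on a
    decimated grid and linearly resized back, which is exact for constant
    images and much faster than full-resolution filtering."""
    step = int(sigma_px // 8)
    if step < 2:
        return ndimage.gaussian_filter(pixels, sigma=sigma_px, mode="nearest")
    from skimage.transform import resize

    small = pixels[::step, ::step]
    low = ndimage.gaussian_filter(small, sigma=sigma_px / step, mode="nearest")
    return resize(low, pixels.shape, order=1, mode="edge", anti_aliasing=False)


def autofluorescence_mask(
    af_img: ChannelImage, spec: ThresholdSpec, dilation_px: int = 1
) -> np.ndarray:
    """Threshold the unlabeled autofluorescence channel and dilate the result.

    The dilation (default one pixel) swallows the dim halo rims around
    autofluorescent granules that sit below threshold but above the marker
    detection level.
    """
    if af_img.role != "autofluorescence":
        raise ValueError(f"expected an autofluorescence channel, got role {af_img.role!r}")
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    thr = spec.resolve(af_img.pixels, af_img.bit_depth)
    mask = af_img.pixels >= thr
    if dilation_px > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilation_px)
    return mask


def subtract_mask(img: ChannelImage, mask: np.ndarray) -> ChannelImage:
    """Zero every pixel under the mask; leave all others untouched."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {img.shape}")
    out = img.pixels.copy()
    out[mask] = 0.0
    return img.with_pixels(out)


def edge_enhance(
    img: ChannelImage, edge_strength: float, edge_sigma_um: float = 1.0
) -> ChannelImage:
    """High-boost (unsharp) filtering: img + strength * (img - lowpass(img)).

    Sharpens object borders so that a single threshold separates objects from
    the residual background.  Strength 0 is the identity; output is clipped
    to the image's bit range.
    """
    if edge_strength < 0:
        raise ValueError("edge_strength must be >= 0")
    if edge_strength == 0:
        return img
    sigma_px = edge_sigma_um / img.pixel_size_um
    lowpass = ndimage.gaussian_filter(img.pixels, sigma=sigma_px, mode="nearest")
    out = img.pixels + edge_strength * (img.pixels - lowpass)
    return img.with_pixels(np.clip(out, 0, img.intensity_max))


def _component_objects(
    binary: np.ndarray,
    raw: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float,
    max_area_um2: float,
    roundness_range: tuple[float, float],
) -> tuple[list[DetectedObject], np.ndarray]:
    """8-connected components of ``binary`` filtered by area and roundness."""
    px2 = pixel_size_um**2
    labels = cc_label(binary, connectivity=2)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    objects: list[DetectedObject] = []
    lo, hi = roundness_range
    for prop in regionprops(labels, intensity_image=raw):
        area_um2 = prop.area * px2
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        perim_um = prop.perimeter * pixel_size_um
        if perim_um > 0:
            roundness = min(1.0, 4.0 * np.pi * area_um2 / perim_um**2)
        else:  # single pixel / degenerate outline: treat as perfectly round
            roundness = 1.0
        if not (lo <= roundness <= hi):
            continue
        cy, cx = prop.centroid
        keep[prop.label] = True
        objects.append(
            DetectedObject(
                label=prop.label,
                area_um2=float(area_um2),
                perimeter_um=float(perim_um),
                roundness=float(roundness),
                centroid=(float(cx), float(cy)),
                mean_raw_intensity=float(prop.intensity_mean),
            )
        )
    label_mask = np.where(keep[labels], labels, 0)
    return objects, label_mask


def detect_objects(
    img: ChannelImage,
    params: SegmentationParams,
    raw_img: Optional[ChannelImage] = None,
) -> tuple[list[DetectedObject], np.ndarray]:
    """Threshold the (edge-enhanced) image and filter components by size and shape.

    ``img`` is expected to be background-corrected and autofluorescence-
    subtracted (a documented contract, not enforced).  ``raw_img`` supplies
    the intensities reported per object; it defaults to ``img`` itself.
    Returns the retained objects and a label mask with only those objects.
    """
    raw = (raw_img or img).pixels
    thr = params.signal_threshold.resolve(img.pixels, img.bit_depth)
    binary = img.pixels >= thr
    return _component_objects(
        binary,
        raw,
        img.pixel_size_um,
        params.min_area_um2,
        params.max_area_um2,
        params.roundness_range,
    )


def measure_ir_area(
    objects: Sequence[DetectedObject],
    roi_area_um2: float,
    case_id: str = "",
    region: str = "",
    marker: str = "",
) -> MeasurementRecord:
    """Sum object areas into one percent-immunoreactive-area record."""
    if not roi_area_um2 > 0:
        raise ValueError("roi_area_um2 must be > 0")
    total = float(sum(o.area_um2 for o in objects))
    return MeasurementRecord(
        case_id=case_id,
        region=region,
        marker=marker,
        ir_area_percent=100.0 * total / roi_area_um2,
        roi_area_um2=float(roi_area_um2),
        n_objects=len(objects),
    )


def quantify_marker(
    channels: Mapping[str, "ChannelImage | ImageStack"],
    params: SegmentationParams,
    case_id: str = "",
    region: str = "",
) -> MeasurementRecord:
    """Run the full measurement procedure on one section's channels.

    ``channels`` maps roles to images (or z-stacks, which are max-projected
    first) and must contain the ``signal`` and ``autofluorescence`` roles.
    Fully deterministic for fixed inputs and parameters.
    """
    for role in ("signal", "autofluorescence"):
        if role not in channels:
            raise ValueError(f"missing required channel role {role!r}")

    def as_image(ch) -> ChannelImage:
        return project_stack(ch) if isinstance(ch, ImageStack) else ch

    raw_signal = as_image(channels["signal"])
    af = as_image(channels["autofluorescence"])

    signal = correct_background(raw_signal, params.background_sigma_um)
    af_corr = correct_background(af, params.background_sigma_um)
    af_mask = autofluorescence_mask(af_corr, params.af_threshold, params.af_dilation_px)
    cleaned = subtract_mask(signal, af_mask)
    enhanced = edge_enhance(cleaned, params.edge_strength, params.edge_sigma_um)
    objects, _ = detect_objects(enhanced, params, raw_img=raw_signal)
    logger.debug(
        "quantify_marker(%s, %s/%s): af_mask_px=%d, n_objects=%d",
        params.marker_name,
        case_id,
        region,
        int(af_mask.sum()),
        len(objects),
    )
    return measure_ir_area(
        objects, raw_signal.area_um2, case_id=case_id, region=region, marker=params.marker_name
    )


def detect_plaque_cores(
    thios_img: ChannelImage,
    params: SegmentationParams,
    correct: bool = True,
) -> list[DetectedObject]:
    """Plaque-core candidates from the ThioflavinS channel.

    Plain thresholding followed by a minimum-area restriction — no edge
    enhancement.  Plaque cores are large and intensely ThioS-positive;
    tangles are small and only weakly labeled, so they fall below the size
    cutoff (and largely below threshold).  ``correct`` applies the standard
    background correction first.
    """
    if thios_img.role != "thios":
        raise ValueError(f"expected a thios channel, got role {thios_img.role!r}")
    img = correct_background(thios_img, params.background_sigma_um) if correct else thios_img
    thr = params.signal_threshold.resolve(img.pixels, img.bit_depth)
    binary = img.pixels >= thr
    objects, _ = _component_objects(
        binary,
        thios_img.pixels,
        img.pixel_size_um,
        params.min_area_um2,
        params.max_area_um2,
        params.roundness_range,
    )
    return objects
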