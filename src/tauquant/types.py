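"""Core value types shared by the simulator, the quantification pipeline and the stats layer.

The unit of every image operation is a :class:`ChannelImage`: one 2-D grayscale
raster with a channel role (what fluorophore/stain it carries) and a physical
pixel size.  Segmentation settings are bundled per marker in
:class:`SegmentationParams`; the atom of all downstream statistics is a
:class:`MeasurementRecord` — one percent-immunoreactive-area value for one
(case, region, marker).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Channel roles recognised by the pipeline.
ROLES = ("signal", "autofluorescence", "nuclear", "thios")

#: Brain regions of the study design: four isocortical regions plus the
#: allocortical transentorhinal region.
REGIONS = ("TeCtx", "FrCtx", "CiCtx", "OcCtx", "TEntR")

#: The four isocortical regions averaged into the synthetic "Isocortex" value.
ISOCORTEX_REGIONS = ("TeCtx", "FrCtx", "CiCtx", "OcCtx")

#: Braak-stage groups, controls first.
GROUPS = ("control", "I_II", "III_IV", "V_VI")

#: Object classes the simulator renders and tracks.
OBJECT_CLASSES = ("plaque", "tangle", "thread", "lipofuscin", "nucleus")


def _bit_max(bit_depth: int) -> int:
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    return (1 << bit_depth) - 1


@dataclass(frozen=True)
class ChannelImage:
    """One 2-D intensity raster with role and physical calibration.

    Parameters
    ----------
    pixels
        2-D float array of non-negative intensities within the bit-depth range.
    role
        One of :data:`ROLES`.
    pixel_size_um
        Side length of one pixel in micrometres (> 0).
    bit_depth
        8 or 16; bounds the valid intensity range.
    """

    pixels: np.ndarray
    role: str
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        vmax = _bit_max(self.bit_depth)
        if px.size and (px.min() < 0 or px.max() > vmax):
            raise ValueError(
                f"intensities out of range [0, {vmax}] for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def intensity_max(self) -> int:
        """Largest representable intensity for this bit depth."""
        return _bit_max(self.bit_depth)

    @property
    def area_um2(self) -> float:
        """Physical area covered by the full raster."""
        return float(self.pixels.size) * self.pixel_size_um**2

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Same metadata, new raster (values are clipped-checked by the ctor)."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class ImageStack:
    """An ordered list of same-role, same-shape planes captured at distinct z-levels."""

    planes: Sequence[ChannelImage]

    def __post_init__(self) -> None:
        if len(self.planes) == 0:
            raise ValueError("an ImageStack needs at least one plane")
        first = self.planes[0]
        for p in self.planes[1:]:
            if p.shape != first.shape:
                raise ValueError("all planes must share dimensions")
            if p.role != first.role:
                raise ValueError("all planes must share the channel role")

    def __len__(self) -> int:
        return len(self.planes)


@dataclass(frozen=True)
class ThresholdSpec:
    """How to pick an intensity threshold: a fixed value or Otsu's method."""

    method: str = "otsu"
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "otsu"):
            raise ValueError(f"method must be 'fixed' or 'otsu', got {self.method!r}")
        if self.method == "fixed" and self.value is None:
            raise ValueError("fixed threshold requires a value")

    def resolve(self, pixels: np.ndarray, bit_depth: int = 16) -> float:
        """Return the numeric threshold for ``pixels``."""
        if self.method == "fixed":
            assert self.value is not None
            if not 0 <= self.value <= _bit_max(bit_depth):
                raise ValueError(
                    f"fixed threshold {self.value} outside bit range for depth {bit_depth}"
                )
            return float(self.value)
        from skimage.filters import threshold_otsu

        flat = np.asarray(pixels, dtype=np.float64)
        if np.ptp(flat) == 0:  # constant image: everything below "threshold"
            return float(flat.flat[0]) + 1.0 if flat.size else 0.0
        return float(threshold_otsu(flat))


@dataclass(frozen=True)
class SegmentationParams:
    """All tunables of the measurement procedure for one marker.

    Every numeric value here is configuration, not a constant of the method:
    thresholds and size/shape bounds are calibrated per marker and logged with
    each run so results stay reproducible.

    Attributes
    ----------
    background_sigma_um
        Gaussian scale of the lowpass background estimate.  Should be well
        above (roughly 5x) the diameter of the largest object of interest so
        the estimate tracks illumination, not objects.
    af_threshold, af_dilation_px
        Threshold for the unlabeled autofluorescence channel and the number of
        one-pixel dilations applied to its mask before subtraction (suppresses
        sub-threshold halo rims around autofluorescent granules).
    edge_strength
        High-boost gain of the edge-enhancement step; 0 disables it.
    edge_sigma_um
        Small lowpass scale used inside the high-boost filter.
    signal_threshold
        Threshold applied to the edge-enhanced signal image.
    min_area_um2, max_area_um2, roundness_range
        Size and shape restrictions on connected components.
    """

    marker_name: str = "marker"
    background_sigma_um: float = 50.0
    af_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("otsu"))
    af_dilation_px: int = 1
    edge_strength: float = 1.0
    edge_sigma_um: float = 1.0
    signal_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("otsu"))
    min_area_um2: float = 5.0
    max_area_um2: float = 1e4
    roundness_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not self.background_sigma_um > 0:
            raise ValueError("background_sigma_um must be > 0")
        if self.af_dilation_px < 0:
            raise ValueError("af_dilation_px must be >= 0")
        if self.edge_strength < 0:
            raise ValueError("edge_strength must be >= 0")
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        lo, hi = self.roundness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("roundness_range must be within [0, 1]")


@dataclass(frozen=True)
class DetectedObject:
    """One retained connected component.

    ``roundness`` is the isoperimetric shape factor 4*pi*area/perimeter^2 — 1
    for a disc, smaller for elongated objects.  On a pixel grid small objects
    can nominally exceed 1; values are clipped to 1.  ``mean_raw_intensity``
    is measured on the raw (pre-enhancement) image, so reported intensities
    refer to the original signal rather than the filtered one.
    """

    label: int
    area_um2: float
    perimeter_um: float
    roundness: float
    centroid: tuple[float, float]  # (x, y), 0-based, origin top-left
    mean_raw_intensity: float


@dataclass(frozen=True)
class MeasurementRecord:
    """Percent immunoreactive area of one (case, region, marker) section."""

    case_id: str
    region: str
    marker: str
    ir_area_percent: float
    roi_area_um2: float
    n_objects: int

    def __post_init__(self) -> None:
        if not self.roi_area_um2 > 0:
            raise ValueError("roi_area_um2 must be > 0")
        if not 0.0 <= self.ir_area_percent <= 100.0:
            raise ValueError("ir_area_percent must lie in [0, 100]")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
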