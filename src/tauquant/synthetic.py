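"""Synthetic multi-channel section generator with exact ground truth.

Emulates the content of an immunofluorescently labeled cortical section as
seen by a widefield microscope at low magnification: tangle-like somatic
blobs and thin neuropil threads in the tau-marker channel, large bright
plaque cores in the ThioflavinS channel, lipofuscin granules that appear in
*every* channel (the defining property of autofluorescence and the main
confounder the measurement pipeline has to remove), nuclei in the
counterstain channel, a smooth illumination gradient, and shot plus read
noise.  Each generated section carries per-class binary masks and exact area
fractions, so the quantification pipeline can be validated against known
truth without any human tissue.

Object burden is specified as a target area fraction per class; the
generator places objects until the realized (pixel-counted) fraction
approaches the target, sizing the last object of each class to the remaining
deficit where the configured size range allows.  Overlaps between classes
are resolved by a fixed priority order (plaque > tangle > thread >
lipofuscin > nucleus); ground-truth fractions are computed from the final,
disjoint masks and are therefore exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import GROUPS, OBJECT_CLASSES, REGIONS, ChannelImage

#: Overlap priority: earlier classes keep contested pixels.
CLASS_PRIORITY = ("plaque", "tangle", "thread", "lipofuscin", "nucleus")

_SEED_STRIDE = 1_000_003  # sub-seed counter scheme: (master * stride + index) mod 2^31


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-section sub-seed from one master seed and a counter."""
    return (int(master_seed) * _SEED_STRIDE + int(index)) % (2**31)


@dataclass(frozen=True)
class SectionSimParams:
    """Geometry, optics and noise settings of the simulator.

    Object sizes are deliberately configuration, not biology facts: the
    defaults below (tangle somata 15-25 um across with an elongation of
    roughly 1:3, plaque cores 30-80 um, lipofuscin granules 2-6 um, threads
    1-2 um wide) give the size/shape separability that threshold + size
    filtering relies on, and every range can be overridden.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    # fixed fallback counts, used only for classes without a burden target
    n_tangles: int = 0
    n_threads: int = 0
    n_plaques: int = 0
    n_lipofuscin: int = 0
    n_nuclei: int = 0
    tangle_diameter_um: tuple[float, float] = (15.0, 25.0)
    tangle_aspect_range: tuple[float, float] = (0.28, 0.35)
    plaque_diameter_um: tuple[float, float] = (30.0, 80.0)
    lipofuscin_diameter_um: tuple[float, float] = (2.0, 6.0)
    nucleus_diameter_um: tuple[float, float] = (6.0, 10.0)
    thread_length_um: tuple[float, float] = (15.0, 60.0)
    thread_width_um: tuple[float, float] = (1.0, 2.0)
    signal_intensity: float = 3000.0
    af_intensity: float = 3000.0
    nuclear_intensity: float = 2000.0
    background_level: float = 200.0
    gradient_amplitude: float = 0.15  # fraction of background_level
    poisson_scale: float = 1.0  # photons per intensity count; 0 disables shot noise
    gaussian_sd: float = 10.0  # read noise, counts
    tangle_thios_brightness_factor: float = 0.3

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in ("n_tangles", "n_threads", "n_plaques", "n_lipofuscin", "n_nuclei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "tangle_diameter_um",
            "tangle_aspect_range",
            "plaque_diameter_um",
            "lipofuscin_diameter_um",
            "nucleus_diameter_um",
            "thread_length_um",
            "thread_width_um",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if not 0 < self.tangle_thios_brightness_factor < 1:
            raise ValueError("tangle_thios_brightness_factor must lie in (0, 1)")
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class StageBurdenProfile:
    """Target area fraction per object class for one Braak-stage group."""

    group: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for cls, f in self.fractions.items():
            if cls not in OBJECT_CLASSES:
                raise ValueError(f"unknown object class {cls!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {cls!r} must lie in [0, 1]")
        if sum(self.fractions.values()) > 0.5:
            raise ValueError(
                "summed class fractions exceed 0.5; objects cannot pack that densely"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Per-class binary masks and the exact area fraction of each class."""

    masks: Mapping[str, np.ndarray]
    true_area_fraction: Mapping[str, float]

    def mask(self, cls: str) -> np.ndarray:
        return np.asarray(self.masks[cls], dtype=bool)


@dataclass(frozen=True)
class SimulatedSection:
    """One generated section: channel images, ground truth, and provenance."""

    channels: Mapping[str, ChannelImage]
    ground_truth: GroundTruth
    seed: int
    params: SectionSimParams
    case_id: str = ""
    region: str = ""
    mosaic: int = 0


# ---------------------------------------------------------------------------
# object rendering
# ---------------------------------------------------------------------------


def _patch_slices(cy: int, cx: int, half: int, shape: tuple[int, int]):
    y0, y1 = max(0, cy - half), min(shape[0], cy + half + 1)
    x0, x1 = max(0, cx - half), min(shape[1], cx + half + 1)
    return (slice(y0, y1), slice(x0, x1))


def _draw_tangle(rng: np.random.Generator, shape, px_um, d_um, aspect):
    """Anisotropic Gaussian blob cut at half maximum: a rotated ellipse whose
    interior carries the (truncated) Gaussian profile in [0.5, 1]."""
    d_px = d_um / px_um
    a_px, b_px = d_px / 2.0, aspect * d_px / 2.0
    theta = rng.uniform(0, np.pi)
    cy = rng.integers(0, shape[0])
    cx = rng.integers(0, shape[1])
    half = int(math.ceil(a_px)) + 2
    sl = _patch_slices(cy, cx, half, shape)
    yy, xx = np.mgrid[sl]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    # Gaussian with half-max at the ellipse boundary: exp(-ln2 * r2), r2 = 1 on it
    r2 = (u / a_px) ** 2 + (v / b_px) ** 2
    profile = np.exp(-math.log(2.0) * r2)
    mask = r2 <= 1.0
    return sl, mask, np.where(mask, profile, 0.0)


def _draw_disc(rng: np.random.Generator, shape, px_um, d_um):
    r_px = d_um / px_um / 2.0
    cy = rng.integers(0, shape[0])
    cx = rng.integers(0, shape[1])
    half = int(math.ceil(r_px)) + 1
    sl = _patch_slices(cy, cx, half, shape)
    yy, xx = np.mgrid[sl]
    rr = np.hypot(yy - cy, xx - cx)
    mask = rr <= r_px
    return sl, mask, rr, r_px


def _draw_plaque(rng: np.random.Generator, shape, px_um, d_um):
    """Radially structured disc: bright plateau core, dimmer skirt out to the rim."""
    sl, mask, rr, r_px = _draw_disc(rng, shape, px_um, d_um)
    core = rr <= 0.45 * r_px
    with np.errstate(invalid="ignore"):
        skirt = 0.7 - 0.2 * np.clip((rr - 0.45 * r_px) / (0.55 * r_px + 1e-9), 0, 1)
    profile = np.where(core, 1.0, skirt)
    return sl, mask, np.where(mask, profile, 0.0)


def _draw_thread(rng: np.random.Generator, shape, px_um, length_um, width_um):
    """Random-walk polyline dilated to the thread width."""
    from scipy.ndimage import binary_dilation
    from skimage.draw import line

    length_px = max(2, int(round(length_um / px_um)))
    canvas = np.zeros(shape, dtype=bool)
    y = float(rng.integers(0, shape[0]))
    x = float(rng.integers(0, shape[1]))
    theta = rng.uniform(0, 2 * np.pi)
    step = 4.0
    travelled = 0.0
    while travelled < length_px:
        theta += rng.normal(0.0, 0.45)
        ny = y + step * math.sin(theta)
        nx = x + step * math.cos(theta)
        rr, cc = line(int(round(y)), int(round(x)), int(round(ny)), int(round(nx)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[keep], cc[keep]] = True
        travelled += step
        y, x = ny, nx
    r = max(0, int(round(width_um / px_um / 2.0)))
    if r > 0:
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        canvas = binary_dilation(canvas, structure=(yy**2 + xx**2) <= r**2)
    return canvas


# ---------------------------------------------------------------------------
# burden-driven placement
# ---------------------------------------------------------------------------


def _expected_area_um2(cls: str, p: SectionSimParams, d_um: float, extra: float) -> float:
    if cls == "tangle":
        return math.pi / 4.0 * d_um * (extra * d_um)
    if cls in ("plaque", "lipofuscin", "nucleus"):
        return math.pi / 4.0 * d_um**2
    if cls == "thread":
        return d_um * extra  # length * width
    raise ValueError(cls)


def _min_area_px(cls: str, p: SectionSimParams) -> float:
    px2 = p.pixel_size_um**2
    if cls == "tangle":
        return _expected_area_um2(cls, p, p.tangle_diameter_um[0], p.tangle_aspect_range[0]) / px2
    if cls == "plaque":
        return _expected_area_um2(cls, p, p.plaque_diameter_um[0], 0) / px2
    if cls == "lipofuscin":
        return _expected_area_um2(cls, p, p.lipofuscin_diameter_um[0], 0) / px2
    if cls == "nucleus":
        return _expected_area_um2(cls, p, p.nucleus_diameter_um[0], 0) / px2
    if cls == "thread":
        return p.thread_length_um[0] * p.thread_width_um[0] / px2
    raise ValueError(cls)


def _fill_class(
    cls: str,
    target_px: Optional[float],
    fallback_count: int,
    claimed: np.ndarray,
    p: SectionSimParams,
    rng: np.random.Generator,
    render: Callable,
):
    """Place objects of one class until the claimed pixel count approaches
    ``target_px`` (or exactly ``fallback_count`` objects when no target is set).

    Returns the class mask and a list of (slice, profile) renders for the
    intensity pass.  Pixels already claimed by a higher-priority class are
    never re-assigned.
    """
    shape = claimed.shape
    mask = np.zeros(shape, dtype=bool)
    renders: list = []
    min_area = _min_area_px(cls, p)

    def place(size_hint_px: Optional[float]) -> int:
        out = render(rng, shape, size_hint_px)
        if out is None:
            return 0
        sl, obj_mask, profile = out
        new = obj_mask & ~claimed[sl] & ~mask[sl]
        gained = int(new.sum())
        if gained:
            mask[sl][new] = True
            renders.append((sl, np.where(new, profile, 0.0)))
        return gained

    if target_px is None:
        for _ in range(fallback_count):
            place(None)
        return mask, renders

    count = 0
    attempts = 0
    max_attempts = 20000
    while target_px - count > 0.5 * min_area and attempts < max_attempts:
        remaining = target_px - count
        count += place(remaining)
        attempts += 1
    return mask, renders


def generate_section(
    params: SectionSimParams,
    burden: StageBurdenProfile,
    seed: int,
    case_id: str = "",
    region: str = "",
    mosaic: int = 0,
) -> SimulatedSection:
    """Render one four-channel section with exact per-class ground truth.

    Deterministic for fixed ``(params, burden, seed)``.  Realized area
    fractions track the burden targets to within the granularity of the
    smallest allowed object of each class.
    """
    p = params
    rng = np.random.default_rng(seed)
    shape = tuple(p.image_size_px)
    n_px = shape[0] * shape[1]
    px_um = p.pixel_size_um
    px2 = px_um**2

    def size_from_hint(cls: str, hint_px: Optional[float], lo: float, hi: float, extra: float) -> float:
        """Sample a diameter/length; if a remaining-area hint is given and the
        sampled object would overshoot it, solve the size for the hint instead."""
        d = rng.uniform(lo, hi)
        if hint_px is not None:
            if cls == "tangle":
                want = math.sqrt(hint_px * px2 / (math.pi / 4.0 * extra))
            elif cls == "thread":
                want = hint_px * px2 / extra
            else:
                want = math.sqrt(hint_px * px2 / (math.pi / 4.0))
            if _expected_area_um2(cls, p, d, extra) > hint_px * px2:
                d = float(np.clip(want, lo, hi))
        return d

    def render_tangle(rng_, shape_, hint):
        aspect = rng_.uniform(*p.tangle_aspect_range)
        d = size_from_hint("tangle", hint, *p.tangle_diameter_um, extra=aspect)
        return _draw_tangle(rng_, shape_, px_um, d, aspect)

    def render_plaque(rng_, shape_, hint):
        d = size_from_hint("plaque", hint, *p.plaque_diameter_um, extra=0)
        return _draw_plaque(rng_, shape_, px_um, d)

    def render_small_disc(lo_hi, profile_value=1.0):
        def _render(rng_, shape_, hint):
            d = size_from_hint("lipofuscin", hint, *lo_hi, extra=0)
            sl, mask, rr, r_px = _draw_disc(rng_, shape_, px_um, d)
            return sl, mask, np.where(mask, profile_value, 0.0)

        return _render

    def render_thread(rng_, shape_, hint):
        w = rng_.uniform(*p.thread_width_um)
        length = size_from_hint("thread", hint, *p.thread_length_um, extra=w)
        canvas = _draw_thread(rng_, shape_, px_um, length, w)
        ys, xs = np.nonzero(canvas)
        if ys.size == 0:
            return None
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        patch = canvas[sl]
        return sl, patch, np.where(patch, 0.9, 0.0)

    renderers = {
        "tangle": render_tangle,
        "plaque": render_plaque,
        "thread": render_thread,
        "lipofuscin": render_small_disc(p.lipofuscin_diameter_um),
        "nucleus": render_small_disc(p.nucleus_diameter_um),
    }
    fallback_counts = {
        "tangle": p.n_tangles,
        "thread": p.n_threads,
        "plaque": p.n_plaques,
        "lipofuscin": p.n_lipofuscin,
        "nucleus": p.n_nuclei,
    }

    claimed = np.zeros(shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    renders: dict[str, list] = {}
    for cls in CLASS_PRIORITY:
        target = burden.fractions.get(cls)
        target_px = None if target is None else target * n_px
        m, r = _fill_class(
            cls, target_px, fallback_counts[cls], claimed, p, rng, renderers[cls]
        )
        masks[cls] = m
        renders[cls] = r
        claimed |= m

    fractions = {cls: float(masks[cls].sum()) / n_px for cls in CLASS_PRIORITY}
    gt = GroundTruth(masks=masks, true_area_fraction=fractions)

    # --- intensity pass -----------------------------------------------------
    def paint(class_weights: Mapping[str, float]) -> np.ndarray:
        img = np.zeros(shape, dtype=np.float64)
        for cls, w in class_weights.items():
            if w == 0:
                continue
            for sl, profile in renders[cls]:
                img[sl] = np.maximum(img[sl], w * profile)
        return img

    sig = p.signal_intensity
    channel_content = {
        "signal": paint({"tangle": sig, "thread": sig, "lipofuscin": p.af_intensity}),
        "autofluorescence": paint({"lipofuscin": p.af_intensity}),
        "nuclear": paint({"nucleus": p.nuclear_intensity, "lipofuscin": p.af_intensity}),
        "thios": paint(
            {
                "plaque": sig,
                "tangle": p.tangle_thios_brightness_factor * sig,
                "lipofuscin": p.af_intensity,
            }
        ),
    }

    # smooth illumination gain: low-order 2-D polynomial, peak |amp|
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    u = xx / max(shape[1] - 1, 1) - 0.5
    v = yy / max(shape[0] - 1, 1) - 0.5
    c = rng.uniform(-1, 1, size=3)
    poly = c[0] * u + c[1] * v + c[2] * u * v
    peak = np.abs(poly).max()
    gain = 1.0 + p.gradient_amplitude * (poly / peak if peak > 0 else poly)

    channels: dict[str, ChannelImage] = {}
    for role, content in channel_content.items():
        expected = gain * (p.background_level + content)
        if p.poisson_scale > 0:
            img = rng.poisson(expected * p.poisson_scale).astype(np.float64) / p.poisson_scale
        else:
            img = expected.copy()
        if p.gaussian_sd > 0:
            img += rng.normal(0.0, p.gaussian_sd, size=shape)
        img = np.clip(img, 0, 65535)
        channels[role] = ChannelImage(img, role=role, pixel_size_um=px_um, bit_depth=16)

    return SimulatedSection(
        channels=channels,
        ground_truth=gt,
        seed=int(seed),
        params=p,
        case_id=case_id,
        region=region,
        mosaic=mosaic,
    )


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

#: Stage-dependent burden multipliers for the tau marker: a monotone increase
#: from controls (sparse threads only) to late stage (dense tangles and
#: threads), strongest in the transentorhinal region where tau pathology
#: begins.  Values are area fractions.
DEFAULT_STAGE_BURDENS: dict[str, dict[str, float]] = {
    "control": {"tangle": 0.0, "thread": 0.0010, "lipofuscin": 0.003},
    "I_II": {"tangle": 0.0012, "thread": 0.0025, "lipofuscin": 0.003},
    "III_IV": {"tangle": 0.005, "thread": 0.007, "lipofuscin": 0.003},
    "V_VI": {"tangle": 0.016, "thread": 0.016, "lipofuscin": 0.003},
}

#: Regional modulation of the stage burdens (transentorhinal > temporal >
#: frontal/occipital > cingulate), applied to tangle and thread targets only.
DEFAULT_REGION_FACTORS: dict[str, float] = {
    "TeCtx": 1.2,
    "FrCtx": 1.0,
    "CiCtx": 0.7,
    "OcCtx": 1.0,
    "TEntR": 1.5,
}


def default_study_design() -> dict[str, dict[str, dict[str, float]]]:
    """Per-group, per-region burden table emulating stage-progressive pathology."""
    design: dict[str, dict[str, dict[str, float]]] = {}
    for group in GROUPS:
        design[group] = {}
        for region in REGIONS:
            f = DEFAULT_REGION_FACTORS[region]
            base = DEFAULT_STAGE_BURDENS[group]
            design[group][region] = {
                cls: (frac * f if cls in ("tangle", "thread") else frac)
                for cls, frac in base.items()
            }
    return design


def generate_study(
    design: Mapping[str, Mapping[str, Mapping[str, float]]],
    n_cases_per_group: int,
    seed: int,
    params: Optional[SectionSimParams] = None,
    n_mosaics: int = 1,
) -> tuple[list[SimulatedSection], pd.DataFrame]:
    """Generate a full factorial study: groups x regions x cases (x mosaics).

    ``design`` maps group -> region -> class -> target area fraction and must
    cover all four Braak-stage groups and all five regions.  Returns the
    sections and a case table (case_id, braak_group, region, mosaic, seed).
    Reproducible from ``(design, seed)``: each section gets a sub-seed from a
    documented counter scheme, so regeneration is order-independent.
    """
    if n_cases_per_group < 0:
        raise ValueError("n_cases_per_group must be >= 0")
    if n_mosaics not in (1, 2):
        raise ValueError("n_mosaics must be 1 or 2")
    for group in GROUPS:
        if group not in design:
            raise ValueError(f"design missing group {group!r}")
        for region in REGIONS:
            if region not in design[group]:
                raise ValueError(f"design missing region {region!r} for group {group!r}")
    params = params or SectionSimParams()

    sections: list[SimulatedSection] = []
    rows: list[dict] = []
    counter = 0
    for gi, group in enumerate(GROUPS):
        for ci in range(n_cases_per_group):
            case_id = f"case{gi * n_cases_per_group + ci + 1:02d}"
            for region in REGIONS:
                burden = StageBurdenProfile(group=group, fractions=design[group][region])
                for mosaic in range(n_mosaics):
                    sub_seed = derive_seed(seed, counter)
                    counter += 1
                    sections.append(
                        generate_section(
                            params, burden, sub_seed, case_id=case_id, region=region, mosaic=mosaic
                        )
                    )
                    rows.append(
                        {
                            "case_id": case_id,
                            "braak_group": group,
                            "region": region,
                            "mosaic": mosaic,
                            "seed": sub_seed,
                        }
                    )
    columns = ["case_id", "braak_group", "region", "mosaic", "seed"]
    return sections, pd.DataFrame(rows, columns=columns)
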