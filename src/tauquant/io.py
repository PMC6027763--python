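"""File formats and run configuration.

Sections travel as multi-page TIFF (one page per channel, fixed role order),
ground-truth masks as PNG, tables as plain UTF-8 comma-separated CSV, and
run configuration as YAML.  Configuration loading is fail-closed: unknown
keys raise, and a validated snapshot is written next to every output so a
run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import SimulatedSection
from .types import ROLES, ChannelImage, MeasurementRecord, SegmentationParams, ThresholdSpec

#: Page order of section TIFFs.
PAGE_ORDER = ("signal", "autofluorescence", "nuclear", "thios")

MEASUREMENT_COLUMNS = (
    "case_id",
    "region",
    "marker",
    "ir_area_percent",
    "n_objects",
    "roi_area_um2",
)


def write_section_tiff(section: SimulatedSection, path: Union[str, Path]) -> Path:
    """Write one section as a 16-bit multi-page TIFF in :data:`PAGE_ORDER`."""
    path = Path(path)
    pages = np.stack(
        [np.round(section.channels[r].pixels).astype(np.uint16) for r in PAGE_ORDER]
    )
    px = section.channels[PAGE_ORDER[0]].pixel_size_um
    tifffile.imwrite(
        path, pages, photometric="minisblack", resolution=(1e4 / px, 1e4 / px), metadata=None
    )
    return path


def read_section_tiff(
    path: Union[str, Path],
    role_map: Sequence[str] = PAGE_ORDER,
    pixel_size_um: float = 0.5,
) -> dict[str, ChannelImage]:
    """Read a multi-page section TIFF into role-keyed channel images.

    ``role_map`` lists the channel role of each page in order; the page count
    must match it exactly.  Bit depth is taken from the stored dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such section file: {path}")
    for role in role_map:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} in role_map")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(role_map):
        raise ValueError(
            f"page/role mismatch in {path.name}: expected {len(role_map)} pages "
            f"for roles {tuple(role_map)}, found {data.shape[0]}"
        )
    bit_depth = 8 if data.dtype == np.uint8 else 16
    return {
        role: ChannelImage(
            data[i].astype(np.float64), role=role, pixel_size_um=pixel_size_um, bit_depth=bit_depth
        )
        for i, role in enumerate(role_map)
    }


def write_ground_truth(section: SimulatedSection, out_dir: Union[str, Path], section_id: str) -> None:
    """Write per-class binary masks as PNG plus a ground_truth.csv row set."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cls, mask in section.ground_truth.masks.items():
        iio.imwrite(
            out_dir / f"{section_id}_gt_{cls}.png",
            (np.asarray(mask, dtype=np.uint8) * 255),
        )
        rows.append(
            {
                "section_id": section_id,
                "class": cls,
                "true_area_fraction": section.ground_truth.true_area_fraction[cls],
            }
        )
    csv_path = out_dir / "ground_truth.csv"
    df = pd.DataFrame(rows)
    if csv_path.exists():
        df = pd.concat([pd.read_csv(csv_path), df], ignore_index=True)
    df.to_csv(csv_path, index=False)


def write_measurements(
    records: Union[Sequence[MeasurementRecord], pd.DataFrame], path: Union[str, Path]
) -> Path:
    """Write measurement records as a schema-stable CSV (header always present)."""
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        extra = [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
        df = df[[c for c in MEASUREMENT_COLUMNS if c in df.columns] + extra]
    else:
        df = pd.DataFrame(
            [dataclasses.asdict(r) for r in records], columns=list(MEASUREMENT_COLUMNS)
        )
        df = df[list(MEASUREMENT_COLUMNS)]
    df.to_csv(path, index=False)
    return path


def read_measurements(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such measurements file: {path}")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_TOP = {"pixel_size_um", "channels", "markers", "stats", "seed", "tauquant_version"}
_KNOWN_STATS = {"alpha", "posthoc", "exclusions"}
_KNOWN_MARKER = {
    "background_sigma_um",
    "af_threshold",
    "af_dilation_px",
    "edge_strength",
    "edge_sigma_um",
    "signal_threshold",
    "min_area_um2",
    "max_area_um2",
    "roundness_range",
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: channel roles, calibration, per-marker
    segmentation settings and stats options."""

    pixel_size_um: float
    channels: tuple[str, ...]
    markers: Mapping[str, SegmentationParams]
    alpha: float = 0.05
    posthoc: str = "auto"
    exclusions: Optional[str] = None
    seed: int = 0


def _threshold_from_config(node) -> ThresholdSpec:
    if isinstance(node, str):
        return ThresholdSpec(node)
    if isinstance(node, (int, float)):
        return ThresholdSpec("fixed", float(node))
    if isinstance(node, dict):
        return ThresholdSpec(node.get("method", "otsu"), node.get("value"))
    raise ValueError(f"cannot interpret threshold spec {node!r}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration (fail-closed on unknown keys)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "pixel_size_um" not in raw:
        raise ValueError("config is missing required key 'pixel_size_um'")
    channels = tuple(raw.get("channels", PAGE_ORDER))
    for role in channels:
        if role not in ROLES:
            raise ValueError(f"unknown channel role {role!r} in config")

    markers: dict[str, SegmentationParams] = {}
    for name, node in (raw.get("markers") or {}).items():
        node = dict(node or {})
        unknown = set(node) - _KNOWN_MARKER
        if unknown:
            raise ValueError(f"unknown keys in marker {name!r}: {sorted(unknown)}")
        kwargs: dict = {"marker_name": name}
        for key, value in node.items():
            if key in ("af_threshold", "signal_threshold"):
                kwargs[key] = _threshold_from_config(value)
            elif key == "roundness_range":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        markers[name] = SegmentationParams(**kwargs)

    stats_node = dict(raw.get("stats") or {})
    unknown = set(stats_node) - _KNOWN_STATS
    if unknown:
        raise ValueError(f"unknown keys under stats: {sorted(unknown)}")
    alpha = float(stats_node.get("alpha", 0.05))
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return RunConfig(
        pixel_size_um=float(raw["pixel_size_um"]),
        channels=channels,
        markers=markers,
        alpha=alpha,
        posthoc=stats_node.get("posthoc", "auto"),
        exclusions=stats_node.get("exclusions"),
        seed=int(raw.get("seed", 0)),
    )


def snapshot_config(config: RunConfig, out_dir: Union[str, Path]) -> Path:
    """Write the validated configuration (and library version) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def spec_dict(s: ThresholdSpec):
        return {"method": s.method, **({"value": s.value} if s.value is not None else {})}

    payload = {
        "tauquant_version": __version__,
        "pixel_size_um": config.pixel_size_um,
        "channels": list(config.channels),
        "markers": {
            name: {
                "background_sigma_um": p.background_sigma_um,
                "af_threshold": spec_dict(p.af_threshold),
                "af_dilation_px": p.af_dilation_px,
                "edge_strength": p.edge_strength,
                "edge_sigma_um": p.edge_sigma_um,
                "signal_threshold": spec_dict(p.signal_threshold),
                "min_area_um2": p.min_area_um2,
                "max_area_um2": p.max_area_um2,
                "roundness_range": list(p.roundness_range),
            }
            for name, p in config.markers.items()
        },
        "stats": {
            "alpha": config.alpha,
            "posthoc": config.posthoc,
            **({"exclusions": config.exclusions} if config.exclusions else {}),
        },
        "seed": config.seed,
    }
    path = out_dir / "run_config.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_reference_cases() -> pd.DataFrame:
    """The bundled 20-case demographic cohort: four Braak-stage groups of five
    cases each, with age, sex, Braak stage, post-mortem delay and fixation time."""
    here = Path(__file__).parent / "data" / "reference_cases.csv"
    df = pd.read_csv(here)
    df["case_id"] = df["case_id"].astype(str)
    return df
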