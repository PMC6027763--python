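"""Calibrated default segmentation settings and whole-study convenience runs.

The fixed thresholds below are calibrated against the synthetic section
generator (whose stain intensities are known); on real images every value is
expected to be re-calibrated per marker and microscope, which is why they
all live in :class:`~tauquant.types.SegmentationParams` rather than in code.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .quantify import detect_plaque_cores, quantify_marker
from .synthetic import (
    SectionSimParams,
    SimulatedSection,
    default_study_design,
    generate_study,
)
from .types import SegmentationParams, ThresholdSpec


def tau_marker_params(
    sim: Optional[SectionSimParams] = None, marker: str = "ptau"
) -> SegmentationParams:
    """Segmentation settings for a tau phosphosite marker channel.

    The signal threshold sits at 25% of the nominal stain intensity in
    background-corrected units — far above the corrected noise floor, far
    below the dimmest rendered object pixel (half of peak, scaled down by the
    illumination gradient and the residual lowpass bias).  No lower roundness
    bound: neuropil threads are highly elongated.
    """
    sim = sim or SectionSimParams()
    return SegmentationParams(
        marker_name=marker,
        background_sigma_um=125.0,  # ~5x the largest tangle diameter
        af_threshold=ThresholdSpec("fixed", 0.5 * sim.af_intensity),
        af_dilation_px=1,
        edge_strength=1.0,
        edge_sigma_um=1.0,
        signal_threshold=ThresholdSpec("fixed", 0.25 * sim.signal_intensity),
        min_area_um2=5.0,
        max_area_um2=1e4,
        roundness_range=(0.0, 1.0),
    )


def plaque_core_params(
    sim: Optional[SectionSimParams] = None, marker: str = "thios"
) -> SegmentationParams:
    """Settings for ThioflavinS plaque-core detection: threshold plus a
    200 um^2 minimum size, which together pass plaque cores (>= 30 um across,
    intensely labeled) and reject tangles (smaller, and only their brightest
    interior crosses the threshold at the weak ThioS labeling of tangles)."""
    sim = sim or SectionSimParams()
    return SegmentationParams(
        marker_name=marker,
        background_sigma_um=125.0,
        af_threshold=ThresholdSpec("fixed", 0.5 * sim.af_intensity),
        af_dilation_px=1,
        edge_strength=0.0,  # plaque cores need no edge boost
        signal_threshold=ThresholdSpec("fixed", 0.18 * sim.signal_intensity),
        min_area_um2=200.0,
        max_area_um2=1e5,
        roundness_range=(0.0, 1.0),
    )


def measure_sections(
    sections: Sequence[SimulatedSection],
    params: Optional[SegmentationParams] = None,
) -> pd.DataFrame:
    """Quantify the tau-marker channel of every section into one table."""
    rows = []
    for sec in sections:
        p = params or tau_marker_params(sec.params)
        rec = quantify_marker(sec.channels, p, case_id=sec.case_id, region=sec.region)
        rows.append(
            {
                "case_id": rec.case_id,
                "region": rec.region,
                "marker": rec.marker,
                "mosaic": sec.mosaic,
                "ir_area_percent": rec.ir_area_percent,
                "roi_area_um2": rec.roi_area_um2,
                "n_objects": rec.n_objects,
            }
        )
    return pd.DataFrame(rows)


def run_simulated_study(
    n_cases_per_group: int = 5,
    seed: int = 0,
    sim_params: Optional[SectionSimParams] = None,
    seg_params: Optional[SegmentationParams] = None,
    design=None,
    n_mosaics: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full study and measure it: returns (measurements, case table).

    The measurement table carries the braak_group column joined from the
    case table, ready for the stats layer.
    """
    sim_params = sim_params or SectionSimParams(image_size_px=(256, 256))
    design = design or default_study_design()
    sections, cases = generate_study(
        design, n_cases_per_group, seed, params=sim_params, n_mosaics=n_mosaics
    )
    measurements = measure_sections(sections, seg_params or tau_marker_params(sim_params))
    groups = cases[["case_id", "braak_group"]].drop_duplicates()
    measurements = measurements.merge(groups, on="case_id", how="left")
    return measurements, cases
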