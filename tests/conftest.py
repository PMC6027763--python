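import numpy as np
import pandas as pd
import pytest

import tauquant as tq


@pytest.fixture(scope="session")
def sim_params():
    return tq.SectionSimParams()


@pytest.fixture(scope="session")
def mixed_section(sim_params):
    """One 512^2 section with tangles, threads and lipofuscin (seed frozen)."""
    burden = tq.StageBurdenProfile(
        "V_VI", {"tangle": 0.02, "thread": 0.01, "lipofuscin": 0.003}
    )
    return tq.generate_section(sim_params, burden, seed=42)


@pytest.fixture(scope="session")
def lipofuscin_only_section(sim_params):
    """Signal burden zero: the only bright objects appear in every channel."""
    burden = tq.StageBurdenProfile("control", {"lipofuscin": 0.01})
    return tq.generate_section(sim_params, burden, seed=7)


@pytest.fixture(scope="session")
def reference_cases():
    return tq.load_reference_cases()


def make_measurement_table(rng, groups=tq.GROUPS, regions=tq.REGIONS, n=5, shift=None):
    """Balanced factorial table of synthetic ir_area_percent values."""
    rows = []
    for g in groups:
        for r in regions:
            mu = 1.0 if shift is None else shift.get((g, r), 1.0)
            for i in range(n):
                rows.append(
                    {
                        "case_id": f"{g}_{i}",
                        "braak_group": g,
                        "region": r,
                        "marker": "ptau",
                        "ir_area_percent": abs(mu + rng.normal(0, 0.2)),
                    }
                )
    return pd.DataFrame(rows)
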