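import numpy as np
import pytest

import gaitspan as g
from gaitspan.smooth_basis import SmoothTermSpec
from gaitspan.synthetic_data import BurstSpec, WaveformTemplate, default_templates


def age_free_templates():
    """Templates whose burst amplitudes do not depend on age (null cohorts)."""
    out = {}
    for j, t in default_templates().items():
        out[j] = WaveformTemplate(j, tuple(
            BurstSpec(b.name, b.center, b.width, b.base, b.speed_coef,
                      0.0, 0.0, b.age_peak)
            for b in t.bursts
        ))
    return out


@pytest.fixture(scope="session")
def hip_cohort():
    """A small 4-study hip cohort with its ground truth."""
    cfg = g.CohortConfig(n_subjects_per_study=5, joints=("hip",), seed=42)
    data, truth = g.simulate_cohort(cfg)
    return data, truth


@pytest.fixture(scope="session")
def hip_model(hip_cohort):
    """A fitted location-scale model on the small hip cohort."""
    data, _ = hip_cohort
    structure = g.ModelStructure(mean_terms=[
        SmoothTermSpec(("cycle",), (12,)),
        SmoothTermSpec(("age",), (5,)),
    ])
    return g.fit_location_scale(data, structure, joint="hip")
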