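import numpy as np
import pytest

from elbowaxis.io import analyze_specimen
from elbowaxis.synthetic import SyntheticSpec, generate_specimen


def null_spec(**kw):
    return SyntheticSpec(flexion_deg=0.0, varus_deg=0.0, external_deg=0.0,
                         medial_offset_mm=(0.0, 0.0, 0.0),
                         lateral_offset_mm=(0.0, 0.0, 0.0),
                         landmark_jitter_mm=0.0, **kw)


@pytest.fixture(scope="session")
def null_specimen():
    """Zero-misalignment, zero-jitter phantom."""
    return generate_specimen(null_spec(seed=11))


@pytest.fixture(scope="session")
def table_specimen():
    """Phantom constructed at the cohort-mean misalignments, zero jitter."""
    return generate_specimen(SyntheticSpec(landmark_jitter_mm=0.0, seed=7))


@pytest.fixture(scope="session")
def jittered_specimen():
    """Cohort-mean phantom with realistic 0.5 mm landmark picking noise."""
    return generate_specimen(SyntheticSpec(landmark_jitter_mm=0.5, seed=19))


@pytest.fixture(scope="session")
def null_result(null_specimen):
    bone, lm, gt = null_specimen
    return analyze_specimen(bone, lm)


@pytest.fixture(scope="session")
def table_result(table_specimen):
    bone, lm, gt = table_specimen
    return analyze_specimen(bone, lm)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
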