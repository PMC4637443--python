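import numpy as np
import pytest

from ischemia_ecg.anatomy import (SubjectSpec, assign_aha_segments, build_ventricles,
                                  place_electrodes, subject_by_name)
from ischemia_ecg.config import fast_config
from ischemia_ecg.ap import default_endpoints
from ischemia_ecg.study import StudyTable, prepare_subject, run_study


@pytest.fixture(scope="session")
def toy_spec() -> SubjectSpec:
    from ischemia_ecg.fixtures import toy_heart_spec
    return toy_heart_spec()


@pytest.fixture(scope="session")
def toy_heart(toy_spec):
    return assign_aha_segments(build_ventricles(toy_spec))


@pytest.fixture(scope="session")
def default_heart():
    """The thin-walled default subject at 2 mm resolution."""
    return assign_aha_segments(build_ventricles(subject_by_name("D-like", 2.0)))


@pytest.fixture(scope="session")
def endpoints():
    return default_endpoints()


@pytest.fixture(scope="session")
def subject_ctx(endpoints):
    """Prepared default subject: anatomy, electrodes, gain, calibration."""
    return prepare_subject(subject_by_name("D-like", 2.0), 600, endpoints)


@pytest.fixture(scope="session")
def fast_study() -> StudyTable:
    """The desk-scale study: 17 segments x 2 radii x 1 BZ x 1 subject, 2 mm."""
    return run_study(fast_config())


def random_record(rng: np.random.Generator, n_leads: int | None = None,
                  integer: bool = False):
    """A random baseline-corrected multichannel record over the full beat."""
    from ischemia_ecg.forward import ECGRecord
    if n_leads is None:
        n_leads = int(rng.integers(2, 9))
    n_frames = 251
    if integer:
        sig = rng.integers(-200, 201, size=(n_leads, n_frames)).astype(float)
    else:
        sig = rng.normal(0.0, 80.0, size=(n_leads, n_frames))
    return ECGRecord(signals=sig, lead_names=[f"L{i}" for i in range(n_leads)],
                     frame_interval=2.0, scenario_tag="test", baseline_corrected=True)
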