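import dataclasses

import numpy as np
import pytest

from pupilrecover.protocol import build_protocol
from pupilrecover.synth import (
    PupilRecording,
    SubjectRecord,
    default_group_params,
)


@pytest.fixture(scope="session")
def protocol():
    return build_protocol()


@pytest.fixture(scope="session")
def protocol_no_final():
    return build_protocol(final_bright=False)


def make_subject(
    subject_id="ctrl_01",
    group="Control",
    age=75.0,
    seed=1,
    **param_overrides,
) -> SubjectRecord:
    base = default_group_params()[group]
    params = dataclasses.replace(base, **param_overrides) if param_overrides else base
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age_years=age,
        params=params,
        age_reference_years=75.0,
        seed=seed,
    )


@pytest.fixture
def clean_subject():
    """Deterministic subject: no noise, no hippus, no blinks, no dark dilation."""
    return make_subject(
        noise_sd_mm=0.0, hippus_amp_mm=0.0, blink_rate_hz=0.0, dark_gain_mm=0.0
    )


def make_recording(
    diameters, valid=None, t0_ms=0, dt_ms=5, subject_id="s1", eye="left"
) -> PupilRecording:
    """Small hand-built recording on a uniform grid."""
    d = np.asarray(diameters, dtype=float)
    n = len(d)
    if valid is None:
        valid = ~np.isnan(d)
    return PupilRecording(
        subject_id=subject_id,
        eye=eye,
        sample_rate_hz=1000.0 / dt_ms,
        t_ms=t0_ms + dt_ms * np.arange(n, dtype=np.int64),
        diameter_mm=d,
        valid=np.asarray(valid, dtype=bool),
    )
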