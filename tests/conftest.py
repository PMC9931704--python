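import dataclasses

import numpy as np
import pytest

from captoped import CAPTOPRIL, DoseRegimen
from captoped.population import Subject, compute_bsa
from captoped.renal import DEFAULT_OVERLAYS


@pytest.fixture
def adult():
    """70-kg healthy reference adult (GFR 120, overlay attached)."""
    return Subject(
        id="ADULT",
        age=30.0,
        sex="M",
        weight=70.0,
        height=170.0,
        bsa=compute_bsa(70.0, 170.0),
        gfr=120.0,
        ckd_stage="healthy",
        overlay=DEFAULT_OVERLAYS["healthy"],
    )


@pytest.fixture
def child():
    """30-kg healthy child."""
    return Subject(
        id="CHILD",
        age=10.0,
        sex="M",
        weight=30.0,
        height=137.0,
        bsa=compute_bsa(30.0, 137.0),
        gfr=120.0,
        ckd_stage="healthy",
        overlay=DEFAULT_OVERLAYS["healthy"],
    )


@pytest.fixture
def staged_child(child):
    """Factory: the same child moved to a CKD stage at a fixed in-band GFR."""

    def make(stage):
        gfr = {"healthy": 120.0, "mild": 75.0, "moderate": 45.0, "severe": 22.0}[stage]
        return dataclasses.replace(
            child, gfr=gfr, ckd_stage=stage, overlay=DEFAULT_OVERLAYS[stage]
        )

    return make


@pytest.fixture
def dense_regimen():
    """Single 25-mg dose sampled densely to 24 h."""
    return DoseRegimen(amount_mg=25.0, sampling_times=tuple(np.round(np.arange(0.0, 24.01, 0.25), 4)))


@pytest.fixture
def params():
    return CAPTOPRIL
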