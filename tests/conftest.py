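from datetime import datetime

import numpy as np
import pytest

from cardiotel import BeatSeries, ExperimentDesign, PressureBeatSeries


@pytest.fixture
def design() -> ExperimentDesign:
    return ExperimentDesign()


@pytest.fixture
def uniform_beats():
    """Constant 100 ms beat series, 60 s long, anchored at 08:00."""
    rr = np.full(600, 100.0)
    t = np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
    return BeatSeries(t=t, rr=rr, subject_id="m01",
                      anchor=datetime(2022, 2, 7, 8, 0))


def make_pbs(sbp_aligned, rr, rr0=100.0, sbp0=None):
    """Build a PressureBeatSeries from interval-aligned SBP and RR arrays.

    ``sbp_aligned[i]`` is the pressure at the beat terminating interval i;
    beat 0 gets ``sbp0`` (default: first aligned value).
    """
    rr = np.asarray(rr, dtype=float)
    sbp_aligned = np.asarray(sbp_aligned, dtype=float)
    assert len(rr) == len(sbp_aligned)
    t = np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
    sbp = np.concatenate(([sbp_aligned[0] if sbp0 is None else sbp0], sbp_aligned))
    return PressureBeatSeries(beats=BeatSeries(t=t, rr=rr), sbp=sbp, dbp=sbp - 30.0)
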