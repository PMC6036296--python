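import numpy as np
import pytest

from granuflux import (
    InjectionEvent,
    InjectionSchedule,
    KineticTrace,
    RateMeasurement,
)


def make_trace(
    ecar=None,
    ocr=None,
    well_id="A1",
    group="test",
    times=None,
    start_index=1,
):
    """Build a KineticTrace from plain value lists (7.5-min cadence)."""
    n = len(ecar if ecar is not None else ocr)
    if times is None:
        times = [7.5 * (k + 1) for k in range(n)]
    ms = []
    for k in range(n):
        ms.append(
            RateMeasurement(
                well_id=well_id,
                group=group,
                index=start_index + k,
                time_min=times[k],
                ecar=None if ecar is None else float(ecar[k]),
                ocr=None if ocr is None else float(ocr[k]),
            )
        )
    return KineticTrace(well_id=well_id, group=group, measurements=ms)


def schedule(*events):
    return InjectionSchedule(tuple(InjectionEvent(n, a) for n, a in events))


@pytest.fixture
def glyco_trace():
    # baseline [8, 10] | post-GLUC [30, 35, 33] | post-OLIGO [40, 42, 41]
    # | post-2DG [12, 11]
    return make_trace(ecar=[8, 10, 30, 35, 33, 40, 42, 41, 12, 11])


@pytest.fixture
def glyco_schedule():
    return schedule(("GLUC", 2), ("OLIGO", 5), ("2-DG", 8))


@pytest.fixture
def mito_trace():
    # baseline [48, 50] | post-OLIGO [22, 20, 21] | post-FCCP [88, 90, 85]
    # | post-ROT/AA [6, 5]
    return make_trace(ocr=[48, 50, 22, 20, 21, 88, 90, 85, 6, 5])


@pytest.fixture
def mito_schedule():
    return schedule(("OLIGO", 2), ("FCCP", 5), ("ROT/AA", 8))


@pytest.fixture
def rng():
    return np.random.default_rng(20180621)
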