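import numpy as np
import pandas as pd
import pytest

from cytobin import CutoffSet, EventTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_events():
    """A hand-constructed 12-event table with two markers plus an overlay."""
    return EventTable(
        pd.DataFrame(
            {
                "PD-1": [0.1, 0.3, 0.5, 0.7, 1.1, 1.3, 1.5, 1.7, 2.1, 2.3, 2.5, 2.7],
                "IFN-g": [0.1, 0.2, 1.5, 1.6, 0.3, 0.4, 1.7, 1.8, 0.5, 0.6, 1.9, 2.0],
                "IL-21": [0.0, 0.1, 2.0, 2.1, 0.2, 0.3, 2.2, 2.3, 0.4, 0.5, 2.4, 2.5],
            }
        ),
        sample_id="hand",
    )


@pytest.fixture
def cutoffs():
    return CutoffSet(
        cutoffs={"PD-1": 1.0, "IFN-g": 1.0, "IL-21": 1.0},
        hi_cutoffs={"PD-1": 2.0},
    )


def random_event_table(rng, n_events=None, n_markers=None, sample_id="random"):
    """Random EventTable in transformed-unit scale, mixture-free."""
    n = n_events if n_events is not None else int(rng.integers(20, 1500))
    d = n_markers if n_markers is not None else int(rng.integers(2, 8))
    loc = rng.uniform(-0.3, 3.0, size=d)
    scale = rng.uniform(0.1, 1.2, size=d)
    values = rng.normal(loc, scale, size=(n, d))
    names = [f"M{k}" for k in range(d)]
    return EventTable(pd.DataFrame(values, columns=names), sample_id=sample_id)
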