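from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from dokit.catalog import default_catalog


def make_epochs(minute_cpms, start="2019-01-07 08:00:00"):
    """Epoch table whose per-minute VM cpm equals `minute_cpms` exactly.

    Each minute's integer cpm is split across its 4 epochs on the x axis
    only, so sqrt(ax^2+ay^2+az^2) sums are exact.
    """
    rows = []
    t0 = pd.Timestamp(start)
    for m, cpm in enumerate(minute_cpms):
        cpm = int(cpm)
        base, rem = divmod(cpm, 4)
        for e in range(4):
            rows.append(
                {
                    "timestamp": t0 + pd.Timedelta(seconds=15 * (4 * m + e)),
                    "ax": base + (1 if e < rem else 0),
                    "ay": 0,
                    "az": 0,
                }
            )
    return pd.DataFrame(rows)


def make_minutes(cpms, start="2019-01-07 08:00:00"):
    t0 = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "minute_start": [t0 + pd.Timedelta(minutes=i) for i in range(len(cpms))],
            "vm_cpm": [float(c) for c in cpms],
        }
    )


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def a_monday():
    return date(2019, 1, 7)
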