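import datetime as dt

import numpy as np
import pytest

from countercast import (Frequency, InterventionStudy, OutcomeKind,
                         TimeSeriesPanel)


@pytest.fixture
def weekly_panel():
    """Ten weekly rows of proportions with two reference series."""
    rng = np.random.default_rng(0)
    times = [dt.date(2016, 1, 3) + dt.timedelta(weeks=i) for i in range(10)]
    return TimeSeriesPanel(
        times=times,
        focal=rng.uniform(0.1, 0.9, 10),
        references={"a": rng.uniform(0.1, 0.9, 10),
                    "b": rng.uniform(0.1, 0.9, 10)},
        frequency=Frequency.weekly,
        outcome_kind=OutcomeKind.proportion,
    )


@pytest.fixture
def weekly_study(weekly_panel):
    return InterventionStudy(weekly_panel, weekly_panel.times[6])
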