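import numpy as np
import pandas as pd
import pytest

from rwemri.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-cohort simulation shared by read-only tests."""
    cfg = SimConfig(cohorts={"OSTPRE": 120, "ADNI": 60}, seed=42)
    return cfg, simulate_cohort(cfg)


def make_events(*items):
    """Build an events frame from (date, code[, source]) tuples."""
    rows = []
    for item in items:
        date, code = item[0], item[1]
        source = item[2] if len(item) > 2 else "hospital-discharge"
        rows.append(
            {"participant_id": "P1", "event_date": pd.Timestamp(date),
             "source": source, "code": code}
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "event_date", "source", "code"]
    )
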