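import pandas as pd
import pytest

import actipair as ap

T0 = pd.Timestamp("2013-03-04 00:00:00")


def minute_series(values, unit=ap.epochs.UNIT_G, start=T0, device="dev"):
    """Build an EpochSeries from a plain value list (NaN = not recorded)."""
    idx = pd.date_range(start, periods=len(values), freq="min")
    return ap.EpochSeries(device, unit, pd.Series(values, index=idx, dtype=float))


@pytest.fixture(scope="session")
def study_cohort():
    """Small study-like cohort: noise, offsets, gaps and nonwear all active."""
    cfg = ap.CohortConfig(n_participants=8, protocol_days=3, seed=101)
    return ap.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_result(study_cohort):
    return ap.run_study(ap.manifest_from_cohort(study_cohort))


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = ap.CohortConfig.noiseless(n_participants=5, protocol_days=2, seed=202)
    return ap.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_cohort):
    return ap.run_study(ap.manifest_from_cohort(noiseless_cohort))
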