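"""Shared fixtures: programmatically generated trial datasets."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nisurv import SurvivalSummary, TrialData, fit_exponential

LN2 = math.log(2.0)


def metastatic_trial_data() -> TrialData:
    """A 66-patient trial with 54 events and total exposure 54*12/ln2.

    Reproduces the worked metastatic final analysis: the exponential MLE
    depends only on the event count and total exposure, so equal per-patient
    exposures carry no loss of generality.
    """
    n, d = 66, 54
    exposure = d * 12.0 / LN2
    times = np.full(n, exposure / n)
    events = np.array([1] * d + [0] * (n - d))
    return TrialData(time=times, event=events)


def km_example_data() -> TrialData:
    """Synthetic dataset whose KM 90% median CI lower bound sits between
    the non-inferiority threshold 3.3 and the superiority threshold 4.0."""
    rng = np.random.default_rng(0)
    n, median = 40, 4.5
    event_times = rng.exponential(median / LN2, n)
    censor_times = rng.uniform(6.0, 18.0, n)
    observed = np.minimum(event_times, censor_times)
    flags = (event_times <= censor_times).astype(int)
    return TrialData(time=observed, event=flags)


@pytest.fixture
def metastatic_data() -> TrialData:
    return metastatic_trial_data()


@pytest.fixture
def metastatic_outcome(metastatic_data):
    return fit_exponential(metastatic_data)


@pytest.fixture
def km_data() -> TrialData:
    return km_example_data()


@pytest.fixture
def control12() -> SurvivalSummary:
    return SurvivalSummary.from_median(12.0)
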