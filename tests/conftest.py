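import numpy as np
import pandas as pd
import pytest

from mdjoint.datagen import generate_dataset, recovery_config


def make_subject(
    sid="S1", entry=50.0, exit_age=57.0, event=0, bmi=25.0,
    hrt="never", fh="no", menopause="post", parity="2",
):
    return pd.Series(
        dict(id=sid, entry_age=entry, exit_age=exit_age, event=event, bmi=bmi,
             hrt=hrt, fh=fh, menopause=menopause, parity=parity)
    )


def make_visits(sid="S1", ages=(50.0, 52.0), nd=(120.0, 125.0), d=(30.0, 28.0), bmi=None):
    bmi = bmi if bmi is not None else [np.nan] * len(ages)
    return pd.DataFrame(
        dict(id=sid, age=list(ages), nd_area=list(nd), d_area=list(d), bmi=list(bmi))
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject cohort at the default (bivariate) calibration with the
    raised recovery hazard, reused across read-only tests."""
    cfg = recovery_config(n_subjects=300, seed=42)
    subjects, visits, truth = generate_dataset(cfg)
    return cfg, subjects, visits, truth


@pytest.fixture(scope="session")
def trivariate_cohort():
    cfg = recovery_config(
        n_subjects=250, seed=43, survival_mode="trivariate", bmi_visit_missing_rate=0.3
    )
    subjects, visits, truth = generate_dataset(cfg)
    return cfg, subjects, visits, truth
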