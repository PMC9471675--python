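import numpy as np
import pandas as pd
import pytest

from evmir.io import CtTable, SampleSheet
from evmir.simulate import CohortConfig, generate_cohort, toy_interaction_db


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def noise_free_cohort():
    cfg = CohortConfig(subject_sd=0.0, residual_sd=0.0, spike_sd=0.0, seed=3)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_db():
    return toy_interaction_db()


@pytest.fixture()
def tiny_ct():
    """3 samples × 3 features, hand-set Ct values plus a spike-in."""
    rows = []
    spikes = {"S1": 20.0, "S2": 22.0, "S3": 21.0}
    for s in ("S1", "S2", "S3"):
        rows.append((s, "miR-a", 25.0 + spikes[s] - 21.0, False))
        rows.append((s, "miR-b", 28.0 + spikes[s] - 21.0, False))
        rows.append((s, "ctrl", 24.0 + spikes[s] - 21.0, False))
        rows.append((s, "spike", spikes[s], False))
    df = pd.DataFrame(rows, columns=["sample_id", "feature_id", "ct", "undetermined"])
    fcm = {"miR-a": "target", "miR-b": "target",
           "ctrl": "endogenous_control", "spike": "spike_in"}
    return CtTable(df, fcm)


@pytest.fixture()
def paired_sheet():
    """4 subjects × 2 visits, 2 arms, with covariates."""
    rows = []
    rng = np.random.default_rng(5)
    for i, subj in enumerate(["A", "B", "C", "D"]):
        arm = "PIO" if i < 2 else "PLA"
        for v in ("baseline", "week12"):
            rows.append((f"{subj}_{v}", subj, arm, v, "plasma_EV",
                         100 + rng.normal(0, 5), 42 + rng.normal(0, 2), i % 2))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "arm", "visit", "compartment",
                       "weight_kg", "hematocrit_pct", "metformin"]))
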