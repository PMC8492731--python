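import numpy as np
import pandas as pd
import pytest

from ispy_engine import (PatientRecord, SamplerConfig, TimeMachinePrior,
                         TrialScenario, build_model, sample_posterior,
                         simulate_trial)
from ispy_engine.io_cli import records_from_frame
from ispy_engine.signature_scores import ExpressionMatrix


def trial_records(scenario: TrialScenario):
    """Simulate a trial and return analysis-ready PatientRecords."""
    df = simulate_trial(scenario)
    recs = records_from_frame(df)
    return [PatientRecord(r.patient_id, r.arm, r.hr_status, r.her2_status,
                          r.mp_score, r.randomization_day,
                          0 if r.pcr is None else r.pcr, r.deviation)
            for r in recs]


@pytest.fixture(scope="session")
def default_posterior():
    """One moderate posterior fit at the default study conditions, shared."""
    pats = trial_records(TrialScenario(seed=42, deviation_frac=0.0))
    model = build_model(pats, ["control", "pgm"], TimeMachinePrior(),
                        analysis_day=1800)
    post = sample_posterior(model, SamplerConfig(seed=7, chains=2,
                                                 warmup=400, draws=800))
    return post


@pytest.fixture
def toy_expression():
    """Deterministic 6-gene x 6-patient matrix with an IGF1 anchor."""
    rng = np.random.default_rng(123)
    igf1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    data = {
        "IGF1": igf1,
        "POSG": 2.0 * igf1 + 0.1 * rng.standard_normal(6),
        "NEGG": -igf1 + 0.1 * rng.standard_normal(6),
        "NOIS": rng.standard_normal(6),
        "FLAT": np.full(6, 3.0),
        "IGFBP4": igf1 + 0.2 * rng.standard_normal(6),
    }
    df = pd.DataFrame(data).T
    df.columns = [f"S{i}" for i in range(6)]
    return ExpressionMatrix(values=df)
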