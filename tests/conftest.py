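import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import seromir as sm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

EXPECTED_DIRECTIONS = {"miR-25": 1, "miR-29a": 1, "miR-155": 1, "miR-26b": -1}


def make_two_phase(seed: int, **overrides):
    """Training + validation cohorts from one design family."""
    ct1, m1 = sm.generate_cohort(sm.training_design(seed=seed, **overrides), "training")
    ct2, m2 = sm.generate_cohort(
        sm.validation_design(seed=seed, **overrides), "validation"
    )
    ct = sm.CtTable(pd.concat([ct1.data, ct2.data], ignore_index=True))
    meta = sm.SampleMetadata(pd.concat([m1.data, m2.data], ignore_index=True))
    return ct, meta


def handed_candidates():
    """A fixed 4-marker candidate set, as if from the array screen."""
    return sm.CandidateSet(
        pd.DataFrame(
            {
                "assay_id": ["miR-25", "miR-29a", "miR-155", "miR-26b"],
                "fc_hptpos": [4.0, 4.0, 4.0, 0.25],
                "fc_hptneg": [4.0, 4.0, 4.0, 0.25],
                "fc_within_hpt": [4.0, 4.0, 4.0, 0.25],
                "direction": [1, 1, 1, -1],
            }
        )
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """One seeded training cohort with the default planted markers."""
    design = sm.training_design(seed=7)
    ct, meta = sm.generate_cohort(design, "training")
    return design, ct, meta


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    _, ct, _ = planted_cohort
    return sm.build_expression_matrix(ct)


@pytest.fixture(scope="session")
def trained_study():
    """A full two-phase training run on a seeded planted cohort."""
    ct, meta = make_two_phase(7)
    candidates = sm.select_candidates(
        sm.generate_array_pools(sm.training_design(seed=7))
    )
    config = sm.PipelineConfig(seed=7, n_boot=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, report, confirmation = sm.run_training(ct, meta, candidates, config)
    return ct, meta, candidates, config, model, report, confirmation
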