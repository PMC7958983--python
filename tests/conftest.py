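import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ipvcooc import CohortSpec, ItemCatalog, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog() -> ItemCatalog:
    return ItemCatalog.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-parameter cohort shared across read-only tests."""
    return generate_cohort(CohortSpec(n_survivors=500, seed=11))


@pytest.fixture()
def tiny_matrix_csv(tmp_path):
    """A 4-survivor, 3-item response CSV with one all-zero row."""
    df = pd.DataFrame(
        {"PA1": [0, 2, 0, 4], "PV2": [0, 0, 1, 3], "SV1": [0, 0, 0, 0]},
        index=pd.Index(["a", "b", "c", "d"], name="survivor_id"),
    )
    path = tmp_path / "tiny.csv"
    df.to_csv(path)
    return path


def aligned_scores_and_outcomes(cohort, catalog):
    """Filter a synthetic cohort and align scores, outcomes and truth rows."""
    from ipvcooc import ResponseMatrix, compute_outcome_scores, compute_type_scores, filter_survivors

    rm = filter_survivors(cohort.responses)
    ids = set(rm.survivor_ids)
    keep = np.array([i in ids for i in cohort.responses.survivor_ids])
    scores = compute_type_scores(rm, catalog)
    outcome_rm = ResponseMatrix.from_frame(cohort.outcomes.to_frame().loc[keep])
    outcome_scores = compute_outcome_scores(outcome_rm, cohort.outcome_catalog)
    return rm, scores, outcome_scores, keep
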