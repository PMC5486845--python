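import numpy as np
import pytest

from guanokin import (
    CompartmentParams,
    EmissionModel,
    GutRegion,
    ScoreRecord,
    ScoreTable,
    expected_occurrence_estimates,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_params() -> CompartmentParams:
    return CompartmentParams()


@pytest.fixture(scope="session")
def default_emission() -> EmissionModel:
    return EmissionModel()


@pytest.fixture(scope="session")
def score_table() -> ScoreTable:
    """One seeded synthetic study (34 mites, 28 times, 510 records)."""
    return generate_dataset(seed=7)


@pytest.fixture(scope="session")
def calibrated_estimates():
    """Deterministic expected-count posteriors on the 28 design times."""
    return expected_occurrence_estimates()


def make_uniform_table(score: int = 0, time_min: float = 0.0) -> ScoreTable:
    """Single mite, all 15 regions at one constant score."""
    return ScoreTable(
        [
            ScoreRecord(
                mite_id="m1",
                sex="female",
                time_min=time_min,
                region=r,
                malpighian_score=score,
                lumen_score=0,
            )
            for r in GutRegion
        ]
    )
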