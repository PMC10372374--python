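import numpy as np
import pandas as pd
import pytest

from liveromics import StudyDesign


@pytest.fixture(scope="session")
def study_design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def design_table(study_design) -> pd.DataFrame:
    return study_design.sample_table()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230704)


def balanced_design(n_per_cell: int = 3) -> pd.DataFrame:
    """Small balanced 2x2 design table for closed-form oracles."""
    rows = []
    for g in ("PHG", "PNG"):
        for s in ("F", "M"):
            for i in range(n_per_cell):
                rows.append((f"{g}_{s}{i}", g, s, "biological"))
    return pd.DataFrame(rows, columns=["sample", "group", "sex", "role"])
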