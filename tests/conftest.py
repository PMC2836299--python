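import numpy as np
import pandas as pd
import pytest

from acghdiff import (
    BacClone,
    CallMatrix,
    CloneMap,
    GroupDesign,
    breast_cohort_spec,
    build_default_clone_map,
    call_matrix,
    simulate_cohort,
)
from acghdiff.model import GAIN, LOSS, MISSING, NEUTRAL


@pytest.fixture(scope="session")
def default_map():
    return build_default_clone_map()


@pytest.fixture(scope="session")
def breast_cohort():
    """One simulated breast cohort (24 cell lines vs 35 tumors), seed 1."""
    spec = breast_cohort_spec(seed=1)
    ratios, design, truth = simulate_cohort(spec)
    return spec, ratios, design, truth


@pytest.fixture(scope="session")
def breast_calls(breast_cohort):
    _, ratios, design, _ = breast_cohort
    return call_matrix(ratios), design


@pytest.fixture
def toy_map():
    return CloneMap(
        [
            BacClone("c1", "1", 1_000_000, 1_200_000, "1p15"),
            BacClone("c2", "1", 2_000_000, 2_200_000, "1p15"),
            BacClone("c3", "1", 3_000_000, 3_200_000, "1p14"),
        ],
        genome_label="toy",
    )


def make_calls(state_rows, sample_ids, clone_ids, amplified_rows=None):
    """Small CallMatrix from lists of state codes."""
    state = pd.DataFrame(np.array(state_rows, dtype="int8"),
                         index=pd.Index(clone_ids, name="clone_id"),
                         columns=sample_ids)
    if amplified_rows is None:
        amp = pd.DataFrame(False, index=state.index, columns=state.columns)
    else:
        amp = pd.DataFrame(np.array(amplified_rows, dtype=bool),
                           index=state.index, columns=state.columns)
    return CallMatrix(state=state, amplified=amp)


@pytest.fixture
def toy_design():
    samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    return GroupDesign(pd.Series(["A"] * 4 + ["B"] * 4, index=samples))
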