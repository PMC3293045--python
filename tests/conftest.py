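import numpy as np
import pandas as pd
import pytest

from mirnet.data_io import ExpressionMatrix, StageDesign, study_design


@pytest.fixture
def design22() -> StageDesign:
    """The study's 22-sample arm structure (6 normal, 4 per stage, 4 metastasis)."""
    return study_design()


@pytest.fixture
def two_group_design() -> StageDesign:
    return StageDesign(
        stages=("normal", "tumor"),
        sample_to_stage={"n1": "normal", "n2": "normal", "n3": "normal",
                         "t1": "tumor", "t2": "tumor", "t3": "tumor"},
    )


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """One feature: {1,2,3} vs {4,5,6} (hand-ANOVA F = 13.5)."""
    df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                      index=["feat1"], columns=["n1", "n2", "n3", "t1", "t2", "t3"])
    return ExpressionMatrix(data=df, feature_kind="miRNA")


@pytest.fixture
def small_matrix(design22) -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    samples = list(design22.sample_to_stage)
    data = pd.DataFrame(rng.normal(8, 1, size=(10, len(samples))),
                        index=[f"m{i}" for i in range(10)], columns=samples)
    return ExpressionMatrix(data=data, feature_kind="miRNA")
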