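import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from slea import ExpressionMatrix, GeneModuleSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, un-normalized, with one missing cell."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 0.0],
            "s2": [2.0, 5.0, 0.0],
            "s3": [3.0, 5.0, 0.0],
            "s4": [4.0, np.nan, 4.0],
        },
        index=["GA", "GB", "GC"],
    )
    return ExpressionMatrix(data=data, normalized=False)


@pytest.fixture
def tiny_modules() -> GeneModuleSet:
    return GeneModuleSet(
        modules={"M1": frozenset({"GA", "GC"}), "M2": frozenset({"GB", "GX"})},
        descriptions={"M1": "two mapped genes", "M2": "one mapped gene"},
    )


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
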