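import numpy as np
import pytest

from mirpair.io import ExpressionMatrix, SampleSheet


@pytest.fixture
def sheet_11_9() -> SampleSheet:
    """The study design: 11 responders, 9 non-responders."""
    ids = [f"S{i:02d}" for i in range(1, 21)]
    return SampleSheet(ids, ["R"] * 11 + ["NR"] * 9)


@pytest.fixture
def small_matrix(sheet_11_9) -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.normal(4.0, 0.5, size=(30, 20))
    return ExpressionMatrix(
        [f"f{i:03d}" for i in range(30)], list(sheet_11_9.sample_ids), values
    )
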