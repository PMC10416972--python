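import numpy as np
import pandas as pd
import pytest

from nucyto.io_formats import ExpressionMatrix, SampleSheet


def make_sheet(replicates: int = 3) -> SampleSheet:
    rows = [
        {"sample_id": f"{cond}_{frac}_{r}", "condition": cond,
         "fraction": frac, "replicate": r}
        for cond in ("control", "repeat")
        for frac in ("nuclear", "cytoplasmic")
        for r in range(1, replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


def make_matrix(values: dict[str, list[float]], sheet: SampleSheet) -> ExpressionMatrix:
    """Rows: gene -> values in sheet sample order."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=sheet.sample_ids)
    return ExpressionMatrix(df.astype(float))


@pytest.fixture
def sheet3() -> SampleSheet:
    return make_sheet(3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
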