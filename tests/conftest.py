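import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ethniclass.evaluate import ConfusionMatrix

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_confusions() -> dict[str, ConfusionMatrix]:
    """Published multiclass test-set confusion grids for the two final
    feature sets under the regularized logistic-regression classifier."""
    out = {}
    for key in ("name_location_lr", "name_only_lr"):
        df = pd.read_csv(DATA / f"confusion_{key}.csv", index_col=0)
        out[key] = ConfusionMatrix(list(df.index), df.to_numpy())
    return out


@pytest.fixture(scope="session")
def reference_metric_blocks() -> dict:
    """Published per-class and overall metric rows matching the grids."""
    return json.loads((DATA / "reference_metric_blocks.json").read_text())


@pytest.fixture(scope="session")
def reference_selection_f1() -> dict[str, float]:
    """Published dev-set cross-validation F1 per candidate feature set."""
    return json.loads((DATA / "reference_selection_f1.json").read_text())


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_census() -> pd.DataFrame:
    """A mid-size synthetic census shared by pipeline-level tests."""
    from ethniclass.synthetic import SyntheticConfig, generate

    return generate(SyntheticConfig(n_records=4000, seed=11))
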