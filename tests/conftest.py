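import numpy as np
import pandas as pd
import pytest

from padvoice.pad import list_emotions


@pytest.fixture(autouse=True)
def _quiet_numpy():
    with np.errstate(all="ignore"):
        yield


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    return np.random.default_rng(20240901)


def long_table(female: np.ndarray, male: np.ndarray, feature: str = "x") -> pd.DataFrame:
    """Build a long-format feature table from per-gender subject x state matrices."""
    emotions = [e.label for e in list_emotions()]
    rows = []
    for gender, mat, prefix in (("female", female, "f"), ("male", male, "m")):
        for i in range(mat.shape[0]):
            for j, emo in enumerate(emotions):
                rows.append(
                    {
                        "subject_id": f"{prefix}{i:03d}",
                        "gender": gender,
                        "emotion": emo,
                        "feature": feature,
                        "value": float(mat[i, j]),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def make_long_table():
    return long_table
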