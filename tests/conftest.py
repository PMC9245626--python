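import numpy as np
import pandas as pd
import pytest

from dipmtree import parse_types, validate_dataset

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


def make_continuous(n=60, K=2, seed=0, p=2, interaction=0.0, x1_binary=True):
    """Small continuous-outcome trial: X1 optionally gates an arm contrast."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "X1": rng.integers(0, 2, n) if x1_binary else rng.integers(1, 11, n),
    })
    for j in range(2, p + 1):
        df[f"X{j}"] = rng.integers(1, 11, n)
    arm = rng.integers(0, K, n)
    z = df["X1"].to_numpy() > (0.5 if x1_binary else 5)
    y = rng.normal(0, 1, n) + interaction * (arm == K - 1) * z
    df.insert(0, "treatment", arm)
    df.insert(0, "Y", y)
    types = ["response", "treatment"] + ["binary" if (j == 1 and x1_binary) else "ordinal"
                                         for j in range(1, p + 1)]
    roles = parse_types(types, df.columns)
    return validate_dataset(df, roles)


def make_survival(n=80, K=2, seed=0, p=2, log_hr=0.0, censor=0.3):
    """Small survival trial: X1 > median gates an arm-1 log hazard ratio."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"X{j}": rng.integers(1, 11, n) for j in range(1, p + 1)})
    arm = rng.integers(0, K, n)
    z = (df["X1"] > 5).to_numpy()
    rate = np.exp(log_hr * (arm == 1) * z)
    t = rng.exponential(1.0 / rate)
    c = rng.exponential(1.0 / max(censor, 1e-9), size=n) if censor > 0 else np.full(n, np.inf)
    df.insert(0, "treatment", arm)
    df.insert(0, "delta", (t <= c).astype(int))
    df.insert(0, "Y", np.minimum(t, c))
    types = ["response", "status", "treatment"] + ["ordinal"] * p
    roles = parse_types(types, df.columns, outcome_kind="survival")
    return validate_dataset(df, roles)


@pytest.fixture
def anorexia_path():
    return f"{DATA_DIR}/anorexia.csv"


@pytest.fixture
def gbsg_path():
    return f"{DATA_DIR}/gbsg.csv"
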