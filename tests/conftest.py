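import numpy as np
import pandas as pd
import pytest

from micromature.feature_table import FeatureTable
from micromature.maturity import ParamRange, SearchConfig


@pytest.fixture
def tiny_table() -> FeatureTable:
    """4 samples x 3 species, hand-sized values."""
    data = pd.DataFrame(
        {
            "A": [0.5, 0.0, 0.25, 0.1],
            "B": [0.4, 0.5, 0.25, 0.2],
            "C": [0.0, 0.5, 0.50, 0.3],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(data, "species")


def tiny_search_config(seed: int = 0, n_iterations: int = 4, folds: int = 3) -> SearchConfig:
    """Smallest search that still exercises every selection rule."""
    space = {
        "max_depth": ParamRange(2, 4, integer=True),
        "learning_rate": ParamRange(0.05, 0.3, log=True),
        "n_estimators": ParamRange(20, 60, integer=True),
        "subsample": ParamRange(0.7, 1.0),
        "colsample_bytree": ParamRange(0.5, 1.0),
        "reg_alpha": ParamRange(0.0, 1.0),
        "reg_lambda": ParamRange(0.0, 2.0),
    }
    return SearchConfig(
        space=space,
        n_iterations=n_iterations,
        stage1_folds=folds,
        n_initial=min(3, n_iterations),
        seed=seed,
    )


def make_regression_problem(n=60, p=20, n_signal=3, noise=0.3, seed=0):
    """Planted linear signal in a random feature matrix."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.random((n, p)), columns=[f"f{i:03d}" for i in range(p)],
        index=[f"s{i:03d}" for i in range(n)],
    )
    coefs = np.zeros(p)
    coefs[:n_signal] = [2.0, -1.5, 1.0][:n_signal] if n_signal <= 3 else 1.0
    y = X.to_numpy() @ coefs + rng.normal(0, noise, n)
    return X, y, list(X.columns[:n_signal])
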