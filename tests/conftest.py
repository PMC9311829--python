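import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20181001)


@pytest.fixture
def tiny_tps(tmp_path):
    """Write a small TPS file (optionally with classifiers) and return paths."""

    def _write(records, classifiers=None, name="test.tps"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write(records)
        cls_path = None
        if classifiers is not None:
            cls_path = tmp_path / "classifiers.csv"
            pd.DataFrame(classifiers).to_csv(cls_path, index=False)
        return path, cls_path

    return _write


@pytest.fixture
def small_genotypes():
    """Six individuals, three loci, with one missing call and known counts."""
    from asymlink.popgen import GenotypeTable

    ids = [f"i{j}" for j in range(6)]
    a1 = pd.DataFrame(
        {
            "L1": [10, 10, 12, 12, 10, 12],
            "L2": [5, 5, 5, 5, 5, 5],
            "L3": [8, 9, np.nan, 8, 9, 8],
        },
        index=ids,
        dtype=float,
    )
    a2 = pd.DataFrame(
        {
            "L1": [12, 10, 12, 10, 12, 12],
            "L2": [5, 5, 5, 5, 5, 5],
            "L3": [9, 9, np.nan, 8, 8, 14],
        },
        index=ids,
        dtype=float,
    )
    groups = pd.DataFrame({"location": ["A"] * 3 + ["B"] * 3}, index=ids)
    return GenotypeTable(a1=a1, a2=a2, groups=groups)
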