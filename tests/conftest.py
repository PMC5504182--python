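import numpy as np
import pandas as pd
import pytest

from nmrmetab.containers import FeatureMatrix, SpectraSet


def make_spectra(intensities: np.ndarray, ppm: np.ndarray, groups=None) -> SpectraSet:
    n = intensities.shape[0]
    groups = groups or ["g"] * n
    meta = pd.DataFrame(
        {"group": groups, "tissue": ["t"] * n},
        index=[f"s{i:02d}" for i in range(n)],
    )
    return SpectraSet(ppm=ppm, intensities=intensities, metadata=meta)


def make_fm(values: np.ndarray, groups, feature_names=None, **flags) -> FeatureMatrix:
    n, p = values.shape
    names = feature_names or [f"f{j}" for j in range(p)]
    ids = [f"s{i:02d}" for i in range(n)]
    meta = pd.DataFrame({"group": groups, "tissue": ["t"] * n}, index=ids)
    return FeatureMatrix(
        values=pd.DataFrame(values, index=ids, columns=names), metadata=meta, **flags
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_library():
    from nmrmetab.synthetic import make_default_library

    return make_default_library()
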