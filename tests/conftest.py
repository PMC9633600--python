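import numpy as np
import pandas as pd
import pytest

from srphos import preprocess, synthetic
from srphos.model import NormalizedMatrix


@pytest.fixture(scope="session")
def trafficking_design():
    return synthetic.trafficking_design()


@pytest.fixture(scope="session")
def srp_design():
    return synthetic.srp_design()


@pytest.fixture(scope="session")
def small_dataset(trafficking_design):
    """A small trafficking-arm dataset with ground truth (fixed seed)."""
    return synthetic.gen_phospho_dataset(
        trafficking_design, n_sites=300, seed=11
    )


@pytest.fixture(scope="session")
def preprocessed_small(small_dataset):
    """Filter -> qnorm -> valid-value -> downshift -> z for the small set."""
    table, truth = small_dataset
    filtered, _ = preprocess.filter_sites(table)
    logm = preprocess.log2_intensities(filtered)
    norm = preprocess.quantile_normalize(logm, filtered.design["compartment"])
    kept = preprocess.valid_value_filter(norm.values, filtered.design)
    imputed = preprocess.impute_downshift(
        NormalizedMatrix(kept, norm.groups), seed=11
    )
    med_z, rep_z = preprocess.median_zscore(imputed.values, filtered.design)
    return {
        "filtered": filtered,
        "imputed": imputed,
        "median_z": med_z,
        "replicate_z": rep_z,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, samples=None, sites=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    sites = sites or [f"site{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=sites, columns=samples)
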