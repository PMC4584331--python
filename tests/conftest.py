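import warnings

import numpy as np
import pytest

from episom.datamodel_io import (
    MODALITY_METHYLATION,
    GeneSampleMatrix,
    SampleAnnotation,
    centralize,
)
from episom.som_core import SOMModel, train_som
from episom.synthetic_data import default_paper_like_config, generate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """Paper-like synthetic cohort, fixed seed, shared across the suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(default_paper_like_config(seed=0))


@pytest.fixture(scope="session")
def dmet_model(default_bundle):
    """20x20 DmetSOM trained on the centralized default cohort."""
    dmet = centralize(default_bundle.met)
    return train_som(dmet, 20, 20, epochs=30, seed=11, variant="DmetSOM")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_beta_matrix():
    values = np.array(
        [
            [0.1, 0.9, 0.5],
            [0.2, 0.4, 0.6],
            [0.0, 1.0, 0.3],
        ]
    )
    return GeneSampleMatrix(
        values, ["TP53", "MYC", "EZH2"], ["S1", "S2", "S3"],
        MODALITY_METHYLATION,
    )


@pytest.fixture
def tiny_annotation():
    return SampleAnnotation({"S1": "B", "S2": "T", "S3": "T"})


def make_model(codebook, data, bmu, grid_rows, grid_cols, gene_ids=None,
               sample_ids=None, variant="MetSOM"):
    """Hand-crafted SOMModel for unit tests of downstream operations."""
    codebook = np.asarray(codebook, dtype=float)
    data = np.asarray(data, dtype=float)
    n_samples = codebook.shape[1]
    gene_ids = gene_ids or [f"G{i}" for i in range(data.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samples)]
    return SOMModel(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        codebook=codebook,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        bmu=np.asarray(bmu, dtype=int),
        data=data,
        variant=variant,
        seed=0,
        epochs=1,
        radius_initial=1.0,
        radius_final=1.0,
    )
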