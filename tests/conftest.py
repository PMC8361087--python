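"""Shared fixtures: small synthetic corpora generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from phototrait.pipeline import build_trait_dataset
from phototrait.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A compact informative corpus (~100 images) for pipeline-level tests."""
    spec = SyntheticSpec(
        n_species=30,
        images_per_species=(2, 5),
        image_size=64,
        seed=5,
        c_area=2.0,
        c_green=0.5,
        sigma_noise=0.02,
    )
    return generate_corpus(spec, tmp_path_factory.mktemp("corpus"))


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    """(corpus, split, target_params, bioclim_params) built from small_corpus."""
    split, tparams, bparams = build_trait_dataset(
        small_corpus.trait_csv,
        small_corpus.occurrence_csv,
        small_corpus.climate_dir,
        trait_id="LA",
        max_per_species=8,
        seed=3,
    )
    return small_corpus, split, tparams, bparams


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
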