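"""Shared fixtures: one small synthetic dataset, generated once per session
and written to disk so file-based readers are exercised too."""

from __future__ import annotations

import pytest

from insect_gc import SyntheticConfig, make_dataset
from insect_gc.pipeline import load_dataset, trimmed_alignments
from insect_gc.synthetic_data import write_dataset

SMALL_CONFIG = SyntheticConfig(
    seed=7,
    n_species=4,
    n_chromosomes=2,
    chrom_length_range=(1_200_000, 2_000_000),
    gc_lambda=500_000.0,
    n_sco=30,
    protein_length_range=(320, 480),
)


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    path = tmp_path_factory.mktemp("dataset")
    write_dataset(small_dataset, path)
    return path


@pytest.fixture(scope="session")
def loaded_dataset(small_dataset_dir):
    return load_dataset(small_dataset_dir)


@pytest.fixture(scope="session")
def small_trimmed(loaded_dataset):
    return trimmed_alignments(loaded_dataset)
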