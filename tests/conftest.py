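"""Shared fixtures: a small fast region for unit tests and the full default
panel plus coverage-matched training runs for the end-to-end checks."""

from __future__ import annotations

import pytest

from svkg.evaluation import train_and_evaluate
from svkg.genotyper import FAST_GRID, TrainingConfig
from svkg.kmers import build_kmer_index
from svkg.region import BoxSpec, CassetteSpec, RegionBlueprint, generate_haplotype_panel


@pytest.fixture(scope="session")
def small_blueprint() -> RegionBlueprint:
    """A miniature locus (8 kb, 4 haplotypes) for fast unit tests."""
    return RegionBlueprint(
        region_length=8_000,
        cassette=CassetteSpec(start1=800, start2=2_000, length=1_000, divergence=0.0),
        box_specs=(
            BoxSpec("Z", 100, (3_600, 4_600), divergence=0.03),
            BoxSpec("X", 100, (1_900, 3_100), divergence=0.0),
        ),
        snp_rate=0.002,
        n_haplotypes=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_blueprint):
    return generate_haplotype_panel(small_blueprint)


@pytest.fixture(scope="session")
def small_index(small_panel):
    return build_kmer_index(small_panel, k=15, stride=5)


@pytest.fixture(scope="session")
def default_panel():
    from svkg.region import default_blueprint

    return generate_haplotype_panel(default_blueprint())


@pytest.fixture(scope="session")
def default_index(default_panel):
    return build_kmer_index(default_panel)


@pytest.fixture(scope="session")
def fast_training() -> TrainingConfig:
    return TrainingConfig(grid=FAST_GRID)


@pytest.fixture(scope="session")
def coverage_runs(default_panel, default_index, fast_training):
    """Coverage-matched train/test runs sharing seeds and n_train.

    Keys are coverages; values are (accuracy, confusion matrix, model) from
    240 training and 100 held-out simulated samples at that coverage.
    """
    runs = {}
    for coverage in (10.0, 30.0, 40.0):
        runs[coverage] = train_and_evaluate(
            default_panel, default_index, coverage, n_train=240, n_heldout=100,
            seed=42, training=fast_training,
        )
    return runs


@pytest.fixture(scope="session")
def low_coverage_run(default_panel, default_index, fast_training):
    """The 10x regime at the larger training size, evaluated on 500 samples."""
    return train_and_evaluate(
        default_panel, default_index, 10.0, n_train=360, n_heldout=500,
        seed=42, training=fast_training,
    )
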