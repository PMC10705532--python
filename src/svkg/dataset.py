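"""Simulated, labelled feature datasets for training and evaluation.

One "sample" is a diploid genome (a random ordered pair of panel haplotypes
with one of the six genotypes applied), a simulated paired-end read set at
the requested coverage, and the resulting k-mer feature vector.  Genotype
labels cycle through the six classes so every dataset is balanced; the
haplotype pair and per-sample read seed are drawn from a single generator,
making the whole dataset a deterministic function of (panel, index, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .kmers import KmerIndex, count_kmers, normalize
from .readsim import ReadSimParams, simulate_reads
from .region import HaplotypeTemplate
from .variants import (
    ALL_GENOTYPES,
    Allele,
    DEFAULT_SVS,
    DiploidGenome,
    GenotypeLabel,
    SVDefinition,
    apply_allele,
)

__all__ = ["FeatureDataset", "plan_dataset", "simulate_dataset", "simulate_sample_genome"]


@dataclass
class FeatureDataset:
    """A feature matrix with labels, sample ids and the index hash."""

    X: np.ndarray                  # (n_samples, n_features) float32
    labels: list[GenotypeLabel]
    sample_ids: list[str]
    index_hash: str
    normalizers: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def y_indices(self) -> np.ndarray:
        order = {g: i for i, g in enumerate(ALL_GENOTYPES)}
        return np.array([order[g] for g in self.labels], dtype=np.int64)


class _AlleleCache:
    """Per-template allele sequences, built lazily (deletions are pure slicing)."""

    def __init__(self, panel: list[HaplotypeTemplate], svs: dict[str, SVDefinition]):
        self.panel = panel
        self.svs = svs
        self._cache: dict[tuple[int, Allele], str] = {}

    def sequence(self, idx: int, allele: Allele) -> str:
        key = (idx, allele)
        if key not in self._cache:
            self._cache[key] = apply_allele(self.panel[idx], allele, self.svs).sequence
        return self._cache[key]


def simulate_sample_genome(
    panel: list[HaplotypeTemplate],
    label: GenotypeLabel,
    maternal_idx: int,
    paternal_idx: int,
    svs: dict[str, SVDefinition] | None = None,
    cache: _AlleleCache | None = None,
) -> DiploidGenome:
    svs = DEFAULT_SVS if svs is None else svs
    cache = cache or _AlleleCache(panel, svs)
    return DiploidGenome(
        maternal=cache.sequence(maternal_idx, label.allele1),
        paternal=cache.sequence(paternal_idx, label.allele2),
        label=label,
        template_ids=(panel[maternal_idx].id, panel[paternal_idx].id),
    )


def plan_dataset(panel_size: int, n_samples: int, seed: int) -> list[tuple[GenotypeLabel, int, int, int]]:
    """The deterministic sample plan behind :func:`simulate_dataset`.

    Returns one (label, maternal_idx, paternal_idx, read_seed) tuple per
    sample.  Labels cycle through the six classes; haplotype pairs and read
    seeds come from a single generator seeded with ``seed``.
    """
    rng = np.random.default_rng(seed)
    plan = []
    for i in range(n_samples):
        label = ALL_GENOTYPES[i % len(ALL_GENOTYPES)]
        mi, pi = rng.integers(0, panel_size, size=2)
        read_seed = int(rng.integers(0, 2**31 - 1))
        plan.append((label, int(mi), int(pi), read_seed))
    return plan


def simulate_dataset(
    panel: list[HaplotypeTemplate],
    index: KmerIndex,
    n_samples: int,
    coverage: float,
    seed: int,
    read_params: ReadSimParams | None = None,
    svs: dict[str, SVDefinition] | None = None,
    normalize_mode: str = "raw",
    id_prefix: str = "sim",
) -> FeatureDataset:
    """Simulate ``n_samples`` labelled feature vectors at the given coverage.

    Labels cycle through the six genotype classes (balanced up to remainder);
    haplotype pairs are drawn uniformly with replacement from the panel.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    svs = DEFAULT_SVS if svs is None else svs
    base = read_params or ReadSimParams()
    cache = _AlleleCache(panel, svs)

    plan = plan_dataset(len(panel), n_samples, seed)
    X = np.empty((n_samples, index.n_features), dtype=np.float32)
    labels: list[GenotypeLabel] = []
    ids: list[str] = []
    normalizers = np.empty(n_samples, dtype=np.float64)
    for i, (label, mi, pi, read_seed) in enumerate(plan):
        genome = simulate_sample_genome(panel, label, mi, pi, svs, cache)
        params = dataclasses.replace(base, coverage=coverage, seed=read_seed)
        reads = simulate_reads(genome, params)
        vector = count_kmers(reads, index, sample_id=f"{id_prefix}{i:04d}")
        if normalize_mode != "raw":
            vector = normalize(vector, normalize_mode)
        X[i] = vector.counts
        normalizers[i] = vector.normalizer
        labels.append(label)
        ids.append(vector.sample_id)
    return FeatureDataset(
        X=X, labels=labels, sample_ids=ids, index_hash=index.hash, normalizers=normalizers
    )
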