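"""Evaluation surfaces: confusion matrices, accuracy-vs-coverage grids,
trio Mendelian consistency, and population allele frequencies.

These mirror how alignment-free genotype callers are benchmarked: held-out
simulation accuracy stratified by coverage and training-set size, agreement
tables against an orthogonal assay, the rate of Mendelian-inconsistent trio
calls, and per-superpopulation allele-frequency estimates over unrelated
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import simulate_dataset
from .genotyper import TrainingConfig, predict_matrix, train
from .kmers import KmerIndex
from .readsim import ReadSimParams
from .region import HaplotypeTemplate
from .variants import ALL_GENOTYPES, Allele, GenotypeLabel

__all__ = [
    "ConfusionMatrix",
    "TrioRecord",
    "confusion_and_accuracy",
    "mendelian_check",
    "trio_report",
    "allele_frequencies",
    "train_and_evaluate",
    "accuracy_grid",
]


# ---------------------------------------------------------------------------
# Confusion matrices


@dataclass
class ConfusionMatrix:
    """Truth x predicted counts over a fixed class order."""

    class_order: list
    counts: np.ndarray  # square, rows = truth, columns = predicted

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match class order length")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix has no accuracy")
        return self.n_correct / self.total

    def modal_confusion(self):
        """The off-diagonal (truth, predicted) cell with the largest count."""
        off = self.counts.copy()
        np.fill_diagonal(off, -1)
        i, j = np.unravel_index(int(np.argmax(off)), off.shape)
        return self.class_order[i], self.class_order[j], int(off[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        names = [str(c) for c in self.class_order]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_and_accuracy(
    truth,
    predicted,
    class_order=None,
    sample_ids=None,
    exclude_ids=None,
) -> ConfusionMatrix:
    """Build a confusion matrix from paired truth/prediction label lists.

    ``exclude_ids`` drops samples (by id) before counting — e.g. samples the
    orthogonal assay could not genotype.  Classes default to the six
    genotypes if all labels are genotypes, else to sorted unique labels.
    """
    truth, predicted = list(truth), list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth and prediction lists differ in length: {len(truth)} vs {len(predicted)}"
        )
    if exclude_ids:
        if sample_ids is None:
            raise ValueError("exclude_ids requires sample_ids")
        keep = [i for i, s in enumerate(sample_ids) if s not in set(exclude_ids)]
        truth = [truth[i] for i in keep]
        predicted = [predicted[i] for i in keep]
    if class_order is None:
        observed = set(truth) | set(predicted)
        if observed <= set(ALL_GENOTYPES):
            class_order = [g for g in ALL_GENOTYPES if g in observed] or list(ALL_GENOTYPES)
        else:
            class_order = sorted(observed, key=str)
    idx = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(class_order=list(class_order), counts=counts)


# ---------------------------------------------------------------------------
# Trio consistency


@dataclass(frozen=True)
class TrioRecord:
    child_id: str
    parent1_id: str
    parent2_id: str
    child: GenotypeLabel
    parent1: GenotypeLabel
    parent2: GenotypeLabel


def mendelian_check(trio: TrioRecord) -> bool:
    """True iff the child's alleles can be assigned one to each parent.

    Consistency is over unordered alleles: some assignment sends one child
    allele into parent 1's allele set and the other into parent 2's.
    Symmetric under parent swap and child-allele order.
    """
    c1, c2 = trio.child.alleles
    p1, p2 = set(trio.parent1.alleles), set(trio.parent2.alleles)
    return (c1 in p1 and c2 in p2) or (c2 in p1 and c1 in p2)


def trio_report(trios: list[TrioRecord]) -> pd.DataFrame:
    """Per-trio consistency flags plus the overall inconsistent fraction."""
    rows = [
        {
            "child_id": t.child_id,
            "parent1_id": t.parent1_id,
            "parent2_id": t.parent2_id,
            "child": str(t.child),
            "parent1": str(t.parent1),
            "parent2": str(t.parent2),
            "consistent": mendelian_check(t),
        }
        for t in trios
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_frequencies(
    genotypes: dict[str, GenotypeLabel],
    populations: dict[str, str],
    unrelated: set[str] | None = None,
) -> pd.DataFrame:
    """Per-population and overall allele counts/frequencies for the deletions.

    Only samples in ``unrelated`` (default: all with a population) with a
    genotype call are counted; each sample contributes two alleles to its
    population's denominator.
    """
    if unrelated is None:
        unrelated = set(populations)
    rows = []
    pops = sorted(set(populations.values()))
    for scope in pops + ["ALL"]:
        samples = [
            s
            for s in unrelated
            if s in genotypes and s in populations and (scope == "ALL" or populations[s] == scope)
        ]
        total = 2 * len(samples)
        for allele in (Allele.DEL37, Allele.DEL42):
            count = sum(g.alleles.count(allele) for g in (genotypes[s] for s in samples))
            rows.append(
                {
                    "population": scope,
                    "allele": allele.value,
                    "allele_count": count,
                    "total_alleles": total,
                    "frequency": count / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Accuracy vs coverage / training size


def train_and_evaluate(
    panel: list[HaplotypeTemplate],
    index: KmerIndex,
    coverage: float,
    n_train: int,
    n_heldout: int,
    seed: int,
    training: TrainingConfig | None = None,
    read_params: ReadSimParams | None = None,
    svs=None,
    normalize_mode: str = "raw",
):
    """One coverage-matched train/test cell; returns (accuracy, matrix, model).

    Training and held-out samples are simulated independently (seed and
    seed + a fixed offset), the model is selected by CV on the training set
    only, and accuracy is measured on the held-out set.
    """
    training = training or TrainingConfig()
    train_set = simulate_dataset(
        panel, index, n_train, coverage, seed=seed, read_params=read_params,
        svs=svs, normalize_mode=normalize_mode, id_prefix=f"train{seed}_",
    )
    heldout = simulate_dataset(
        panel, index, n_heldout, coverage, seed=(seed + 777_000_001) % (2**31),
        read_params=read_params, svs=svs, normalize_mode=normalize_mode,
        id_prefix=f"test{seed}_",
    )
    model = train(train_set, config=training)
    predicted = predict_matrix(model, heldout)
    matrix = confusion_and_accuracy(
        heldout.labels, predicted, class_order=list(ALL_GENOTYPES)
    )
    return matrix.accuracy, matrix, model


def accuracy_grid(
    panel: list[HaplotypeTemplate],
    index: KmerIndex,
    coverages: list[float],
    n_train_list: list[int],
    n_heldout: int,
    seeds: list[int],
    training: TrainingConfig | None = None,
    read_params: ReadSimParams | None = None,
    svs=None,
) -> pd.DataFrame:
    """Mean held-out accuracy ± standard error per (coverage, n_train) cell.

    The standard error is computed across independent seed replicates.  A
    degenerate cell (e.g. n_train < 6 so a class is missing) is marked
    invalid and the run continues.
    """
    rows = []
    for coverage in coverages:
        for n_train in n_train_list:
            accs = []
            valid = True
            error = ""
            for seed in seeds:
                try:
                    acc, _, _ = train_and_evaluate(
                        panel, index, coverage, n_train, n_heldout, seed,
                        training=training, read_params=read_params, svs=svs,
                    )
                    accs.append(acc)
                except ValueError as exc:
                    valid = False
                    error = str(exc)
                    break
            if valid and accs:
                mean = float(np.mean(accs))
                se = float(np.std(accs, ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
            else:
                mean, se = float("nan"), float("nan")
            rows.append(
                {
                    "coverage": coverage,
                    "n_train": n_train,
                    "n_heldout": n_heldout,
                    "n_seeds": len(accs),
                    "mean_accuracy": mean,
                    "se_accuracy": se,
                    "valid": valid,
                    "error": error,
                }
            )
    return pd.DataFrame(rows)
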