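"""Confusion arithmetic, trio consistency and allele-frequency estimation."""

import itertools

import numpy as np
import pytest

from svkg.evaluation import (
    ConfusionMatrix,
    TrioRecord,
    accuracy_grid,
    allele_frequencies,
    confusion_and_accuracy,
    mendelian_check,
    trio_report,
)
from svkg.genotyper import TrainingConfig
from svkg.variants import ALL_GENOTYPES, Allele, GenotypeLabel

WT = GenotypeLabel(Allele.WT, Allele.WT)
H37 = GenotypeLabel(Allele.WT, Allele.DEL37)
H42 = GenotypeLabel(Allele.WT, Allele.DEL42)
HOM37 = GenotypeLabel(Allele.DEL37, Allele.DEL37)
HOM42 = GenotypeLabel(Allele.DEL42, Allele.DEL42)
C3742 = GenotypeLabel(Allele.DEL37, Allele.DEL42)


class TestConfusionMatrix:
    def test_cohort_style_matrix_accuracy(self):
        """A 3-class agreement table against an orthogonal assay: 539 of 586
        concordant (92.0%), rising to 569/586 (97%) if the 30 hom-deleted
        assay calls with wild-type predictions are treated as assay failures."""
        counts = np.array([[8, 8, 18], [1, 175, 17], [0, 3, 356]])
        matrix = ConfusionMatrix(class_order=[HOM37, H37, WT], counts=counts)
        assert matrix.total == 586
        assert matrix.n_correct == 539
        assert matrix.accuracy == pytest.approx(539 / 586)
        assert round(100 * matrix.accuracy, 1) == 92.0

        adjusted = (matrix.n_correct + 30) / matrix.total
        assert adjusted == pytest.approx(569 / 586)
        assert round(100 * adjusted) == 97

    def test_identical_lists_give_perfect_accuracy(self):
        labels = [WT, H37, H42, HOM37, C3742, HOM42] * 3
        matrix = confusion_and_accuracy(labels, labels)
        assert matrix.accuracy == 1.0
        off = matrix.counts.copy()
        np.fill_diagonal(off, 0)
        assert not off.any()

    def test_marginals_conserve_sample_count(self):
        rng = np.random.default_rng(40)
        truth = [ALL_GENOTYPES[i] for i in rng.integers(0, 6, size=200)]
        pred = [ALL_GENOTYPES[i] for i in rng.integers(0, 6, size=200)]
        matrix = confusion_and_accuracy(truth, pred, class_order=list(ALL_GENOTYPES))
        assert matrix.total == 200
        assert matrix.counts.sum(axis=1).sum() == 200

    def test_accuracy_invariant_under_class_reordering(self):
        rng = np.random.default_rng(41)
        truth = [ALL_GENOTYPES[i] for i in rng.integers(0, 6, size=120)]
        pred = [ALL_GENOTYPES[i] for i in rng.integers(0, 6, size=120)]
        a = confusion_and_accuracy(truth, pred, class_order=list(ALL_GENOTYPES))
        b = confusion_and_accuracy(truth, pred, class_order=list(ALL_GENOTYPES)[::-1])
        assert a.accuracy == b.accuracy

    def test_exclusion_list_drops_samples(self):
        truth, pred = [WT, WT, H37], [WT, H42, H37]
        matrix = confusion_and_accuracy(
            truth, pred, sample_ids=["a", "b", "c"], exclude_ids={"b"}
        )
        assert matrix.total == 2
        assert matrix.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_and_accuracy([WT], [WT, WT])


class TestMendelian:
    def oracle(self, child, p1, p2):
        """Independent oracle: enumerate transmitted-allele combinations."""
        child_multiset = sorted(child.alleles, key=lambda a: a.value)
        for a1 in p1.alleles:
            for a2 in p2.alleles:
                if sorted((a1, a2), key=lambda a: a.value) == child_multiset:
                    return True
        return False

    def test_forced_transmission_consistent(self):
        trio = TrioRecord("c", "p1", "p2", H37, WT, HOM37)
        assert mendelian_check(trio) is True

    def test_impossible_compound_het_inconsistent(self):
        trio = TrioRecord("c", "p1", "p2", C3742, WT, H37)
        assert mendelian_check(trio) is False

    def test_all_216_combinations_match_exhaustive_oracle(self):
        for child, p1, p2 in itertools.product(ALL_GENOTYPES, repeat=3):
            trio = TrioRecord("c", "a", "b", child, p1, p2)
            assert mendelian_check(trio) == self.oracle(child, p1, p2)

    def test_symmetric_under_parent_swap(self):
        for child, p1, p2 in itertools.product(ALL_GENOTYPES, repeat=3):
            assert mendelian_check(TrioRecord("c", "a", "b", child, p1, p2)) == \
                mendelian_check(TrioRecord("c", "b", "a", child, p2, p1))

    def test_trio_report_lists_inconsistent(self):
        trios = [
            TrioRecord("ok", "m", "f", H37, WT, HOM37),
            TrioRecord("bad", "m", "f", C3742, WT, H37),
        ]
        report = trio_report(trios)
        assert report.consistent.tolist() == [True, False]
        assert (~report.consistent).mean() == 0.5


class TestAlleleFrequencies:
    def test_printed_table_arithmetic(self):
        """282 DEL37 alleles among 1368 -> 20.6%; 390/5142 overall -> 7.6%."""
        assert round(100 * 282 / 1368, 1) == 20.6
        genotypes = {}
        populations = {}
        i = 0
        # AFR: 684 samples (1368 alleles) with 282 DEL37 alleles: 141 hom
        for _ in range(141):
            genotypes[f"s{i}"] = HOM37; populations[f"s{i}"] = "AFR"; i += 1
        for _ in range(684 - 141):
            genotypes[f"s{i}"] = WT; populations[f"s{i}"] = "AFR"; i += 1
        table = allele_frequencies(genotypes, populations)
        row = table[(table.population == "AFR") & (table.allele == "DEL37")].iloc[0]
        assert row.allele_count == 282
        assert row.total_alleles == 1368
        assert round(100 * row.frequency, 1) == 20.6

    def test_hand_counted_example(self):
        """2 het + 1 hom DEL37 among 10 samples -> 4/20 = 20%."""
        genotypes = {f"s{i}": WT for i in range(10)}
        genotypes["s0"] = H37
        genotypes["s1"] = H37
        genotypes["s2"] = HOM37
        populations = {f"s{i}": "POP" for i in range(10)}
        table = allele_frequencies(genotypes, populations)
        row = table[(table.population == "POP") & (table.allele == "DEL37")].iloc[0]
        assert (row.allele_count, row.total_alleles) == (4, 20)
        assert row.frequency == pytest.approx(0.2)

    def test_all_wildtype_gives_zero(self):
        genotypes = {f"s{i}": WT for i in range(5)}
        populations = {f"s{i}": "P" for i in range(5)}
        table = allele_frequencies(genotypes, populations)
        assert (table.frequency == 0).all()

    def test_population_counts_sum_to_overall_and_frequencies_in_unit_interval(self):
        rng = np.random.default_rng(42)
        genotypes = {f"s{i}": ALL_GENOTYPES[rng.integers(0, 6)] for i in range(120)}
        populations = {f"s{i}": ["AFR", "EUR", "EAS"][i % 3] for i in range(120)}
        table = allele_frequencies(genotypes, populations)
        for allele in ("DEL37", "DEL42"):
            sub = table[table.allele == allele]
            per_pop = sub[sub.population != "ALL"].allele_count.sum()
            overall = sub[sub.population == "ALL"].allele_count.iloc[0]
            assert per_pop == overall
        valid = table.frequency.dropna()
        assert ((valid >= 0) & (valid <= 1)).all()

    def test_unrelated_filter_and_missing_genotypes_excluded(self):
        genotypes = {"a": H37, "b": HOM37}
        populations = {"a": "P", "b": "P", "c": "P"}
        table = allele_frequencies(genotypes, populations, unrelated={"a", "c"})
        row = table[(table.population == "P") & (table.allele == "DEL37")].iloc[0]
        # only "a" counts: "b" is related, "c" has no genotype call
        assert (row.allele_count, row.total_alleles) == (1, 2)


class TestAccuracyGrid:
    def test_small_grid_runs_and_marks_degenerate_cells(self, small_panel, small_index):
        training = TrainingConfig(
            n_folds=2,
            grid=({"n_estimators": 25, "max_depth": None, "max_features": "sqrt"},),
        )
        table = accuracy_grid(
            small_panel, small_index,
            coverages=[8.0], n_train_list=[24, 4], n_heldout=12,
            seeds=[1, 2], training=training,
        )
        good = table[(table.n_train == 24)].iloc[0]
        assert good.valid and 0.0 <= good.mean_accuracy <= 1.0
        assert good.n_seeds == 2 and good.se_accuracy >= 0.0
        bad = table[(table.n_train == 4)].iloc[0]
        assert not bad.valid and np.isnan(bad.mean_accuracy)
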