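"""K-mer index construction, counting oracles, normalization and BAM input."""

from collections import Counter

import numpy as np
import pytest

from svkg import dna
from svkg.dataset import simulate_sample_genome
from svkg.kmers import (
    build_kmer_index,
    count_kmers,
    extract_reads_from_bam,
    genotype_template_sequences,
    load_index,
    normalize,
    save_index,
)
from svkg.readsim import ReadPairSet, ReadSimParams, simulate_reads
from svkg.variants import ALL_GENOTYPES, GenotypeLabel, Allele


def brute_count(reads, keys, k) -> np.ndarray:
    """Oracle: naive per-read scan with a Counter."""
    counter = Counter()
    for read in reads:
        for i in range(len(read) - k + 1):
            sub = read[i : i + k]
            if set(sub) - set("ACGT"):
                continue
            counter[min(dna.string_to_kmer(sub), dna.string_to_kmer(dna.revcomp(sub)))] += 1
    return np.array([counter.get(int(v), 0) for v in keys])


class TestIndexConstruction:
    def test_full_list_matches_first_occurrence_oracle(self, small_panel):
        index = build_kmer_index(small_panel, k=15, stride=1)
        seen = {}
        for t in genotype_template_sequences(small_panel):
            seq = t.sequence
            for i in range(len(seq) - 14):
                v = min(
                    dna.string_to_kmer(seq[i : i + 15]),
                    dna.string_to_kmer(dna.revcomp(seq[i : i + 15])),
                )
                seen.setdefault(v, len(seen))
        expected = [v for v, _ in sorted(seen.items(), key=lambda kv: kv[1])]
        assert index.keys.tolist() == expected
        assert index.n_full == len(expected)

    def test_stride_takes_every_nth_key(self, small_panel, small_index):
        full = build_kmer_index(small_panel, k=15, stride=1)
        assert small_index.keys.tolist() == full.keys.tolist()[::5]
        assert small_index.full_positions.tolist() == list(
            range(0, full.n_full, 5)
        )

    def test_full_list_scale_matches_region(self, default_index):
        # the 40 kb locus yields over 40,000 distinct k-mers; every 30th is kept
        assert default_index.n_full > 40_000
        assert default_index.n_features == (default_index.n_full + 29) // 30

    def test_control_keys_single_copy_in_every_genotype_template(self, small_panel):
        index = build_kmer_index(small_panel, k=15, stride=5, max_control_keys=0)
        templates = [t.sequence for t in genotype_template_sequences(small_panel)]
        rng = np.random.default_rng(0)
        for v in rng.choice(index.control_keys, size=50, replace=False):
            for seq in templates:
                assert brute_count([seq], [v], 15)[0] == 1

    def test_invalid_parameters_rejected(self, small_panel):
        with pytest.raises(ValueError, match="k must be >= 11"):
            build_kmer_index(small_panel, k=7)
        with pytest.raises(ValueError, match="stride"):
            build_kmer_index(small_panel, k=15, stride=0)
        with pytest.raises(ValueError, match="empty"):
            build_kmer_index([], k=15)


class TestCounting:
    def test_counts_match_brute_force_on_random_reads(self, small_index):
        rng = np.random.default_rng(12)
        reads = ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(500)]
        vec = count_kmers(reads, small_index)
        expected = brute_count(reads, small_index.keys, small_index.k)
        assert np.array_equal(vec.counts, expected)

    def test_counts_match_brute_force_on_simulated_pairs(self, small_panel, small_index):
        genome = simulate_sample_genome(small_panel, ALL_GENOTYPES[1], 0, 1)
        pairs = simulate_reads(genome, ReadSimParams(coverage=4, seed=13))
        vec = count_kmers(pairs, small_index)
        flat = [s for pair in pairs.sequences() for s in pair]
        expected = brute_count(flat, small_index.keys, small_index.k)
        assert np.array_equal(vec.counts, expected)

    def test_empty_read_set_gives_zero_counts(self, small_index):
        vec = count_kmers([], small_index)
        assert vec.counts.shape == (small_index.n_features,)
        assert not vec.counts.any()

    def test_template_self_count_matches_own_multiset(self, small_panel):
        index = build_kmer_index(small_panel, k=15, stride=1)
        seq = small_panel[0].sequence
        vec = count_kmers([seq], index)
        expected = brute_count([seq], index.keys, 15)
        assert np.array_equal(vec.counts, expected)

    def test_adding_reverse_complements_doubles_every_count(self, small_panel, small_index):
        rng = np.random.default_rng(14)
        reads = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(100)]
        base = count_kmers(reads, small_index).counts
        doubled = count_kmers(reads + [dna.revcomp(r) for r in reads], small_index).counts
        assert np.array_equal(doubled, 2 * base)

    def test_short_reads_skipped(self, small_index):
        vec = count_kmers(["ACGT"], small_index)
        assert not vec.counts.any()

    def test_fastq_path_input(self, small_panel, small_index, tmp_path):
        from svkg.readsim import write_fastq

        genome = simulate_sample_genome(small_panel, ALL_GENOTYPES[0], 0, 0)
        pairs = simulate_reads(genome, ReadSimParams(coverage=3, seed=15))
        r1, r2 = tmp_path / "s_R1.fastq", tmp_path / "s_R2.fastq"
        write_fastq(pairs, r1, r2)
        from_paths = count_kmers((str(r1), str(r2)), small_index)
        in_memory = count_kmers(pairs, small_index)
        assert np.array_equal(from_paths.counts, in_memory.counts)


class TestNormalization:
    def test_raw_mode_is_identity(self, small_index):
        vec = count_kmers(["ACGT" * 30], small_index)
        assert np.array_equal(normalize(vec, "raw").counts, vec.counts)

    def test_wildtype_control_keys_near_two_per_diploid(self, default_panel, default_index):
        genome = simulate_sample_genome(default_panel, ALL_GENOTYPES[0], 0, 1)
        pairs = simulate_reads(genome, ReadSimParams(coverage=30, seed=16))
        vec = normalize(count_kmers(pairs, default_index), "per-haploid-copy")
        mean_control = float(np.mean(vec.control_counts / vec.normalizer))
        assert abs(mean_control - 2.0) < 0.2

    def test_hom_deleted_sample_zeroes_interval_specific_keys(self, default_panel, default_index):
        """Keys found once per wild-type haplotype but absent from the del3.7
        allele drop to ~0 in a DEL37/DEL37 sample."""
        from svkg.variants import DEFAULT_SVS, apply_deletion

        wt = default_panel[0].sequence
        d37 = apply_deletion(default_panel[0], DEFAULT_SVS["del3.7"]).sequence
        wt_counts = brute_count([wt], default_index.keys, default_index.k)
        del_counts = brute_count([d37], default_index.keys, default_index.k)
        specific = (wt_counts == 1) & (del_counts == 0)
        assert specific.sum() > 20

        genome = simulate_sample_genome(default_panel, ALL_GENOTYPES[3], 0, 0)
        pairs = simulate_reads(genome, ReadSimParams(coverage=30, seed=17))
        vec = normalize(count_kmers(pairs, default_index), "per-haploid-copy")
        assert float(vec.counts[specific].mean()) < 0.1

    def test_zero_normalizer_raises_with_advice(self, small_index):
        vec = count_kmers([], small_index)
        with pytest.raises(ValueError, match="raw mode"):
            normalize(vec, "per-haploid-copy")


class TestSerialization:
    def test_roundtrip_preserves_keys_and_hash(self, small_index, tmp_path):
        tsv, js = tmp_path / "i.tsv", tmp_path / "i.json"
        save_index(small_index, tsv, js)
        back = load_index(tsv, js)
        assert back.hash == small_index.hash
        assert np.array_equal(back.keys, small_index.keys)
        assert np.array_equal(np.sort(back.control_keys), np.sort(small_index.control_keys))

    def test_tampered_header_hash_rejected(self, small_index, tmp_path):
        import json

        tsv, js = tmp_path / "i.tsv", tmp_path / "i.json"
        save_index(small_index, tsv, js)
        header = json.loads(js.read_text())
        header["hash"] = "0" * 16
        js.write_text(json.dumps(header))
        with pytest.raises(ValueError, match="hash mismatch"):
            load_index(tsv, js)

    def test_unknown_format_version_rejected(self, small_index, tmp_path):
        import json

        tsv, js = tmp_path / "i.tsv", tmp_path / "i.json"
        save_index(small_index, tsv, js)
        header = json.loads(js.read_text())
        header["format_version"] = 99
        js.write_text(json.dumps(header))
        with pytest.raises(ValueError, match="version"):
            load_index(tsv, js)


@pytest.fixture()
def fixture_bam(tmp_path):
    """A tiny coordinate-sorted, indexed BAM with known pair placement."""
    import pysam

    ref = "".join(np.random.default_rng(20).choice(list("ACGT"), size=600))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chrR", "LN": 600}]}
    reads = []

    def pair(name, pos1, pos2, unmapped2=False):
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = ref[pos1 : pos1 + 50]
        a.flag = 0x1 | 0x40 | (0x8 if unmapped2 else 0x20)
        a.reference_id = 0
        a.reference_start = pos1
        a.mapping_quality = 60
        a.cigar = [(0, 50)]
        b = pysam.AlignedSegment()
        b.query_name = name
        b.reference_id = 0
        b.reference_start = pos2
        if unmapped2:
            b.query_sequence = ref[pos2 : pos2 + 50]
            b.flag = 0x1 | 0x80 | 0x4
            b.cigar = None
        else:
            # aligned reads store SEQ on the forward genome strand
            b.query_sequence = ref[pos2 : pos2 + 50]
            b.flag = 0x1 | 0x80 | 0x10
            b.cigar = [(0, 50)]
            b.mapping_quality = 60
        reads.extend([a, b])

    for i in range(10):
        pair(f"in{i}", 200 + i, 300 + i)
    pair("orphan", 250, 250, unmapped2=True)
    pair("edge", 151, 420)  # read starts at 0-based 151, overlaps base 201 region start? no: ends 201

    path = tmp_path / "t.bam"
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in sorted(reads, key=lambda r: r.reference_start):
            bam.write(r)
    pysam.index(str(path))
    return path, ref


class TestBamExtraction:
    def test_pairs_inside_region_extracted(self, fixture_bam):
        path, ref = fixture_bam
        rs = extract_reads_from_bam(path, "chrR:200-380", flank=0)
        names_expected = 10 + 1 + 1  # in0..in9, orphan, edge (mate in region)
        assert rs.n_pairs == names_expected
        n_reads = len(rs.all_read_codes())
        assert n_reads >= 2 * 10 + 2

    def test_sequences_reoriented_to_read_direction(self, fixture_bam):
        path, ref = fixture_bam
        rs = extract_reads_from_bam(path, "chrR:200-380", flank=0)
        seqs = [s for p in rs.sequences() for s in p if s is not None]
        # reverse-strand mates must come back as the original read, i.e. the
        # reverse complement of the reference slice
        assert dna.revcomp(ref[300 : 300 + 50]) in seqs

    def test_unmapped_mate_of_in_region_read_included(self, fixture_bam):
        path, ref = fixture_bam
        rs = extract_reads_from_bam(path, "chrR:240-260", flank=0)
        seqs = [s for p in rs.sequences() for s in p if s is not None]
        assert ref[250:300] in seqs  # the unmapped mate's stored sequence

    def test_single_base_overlap_included(self, fixture_bam):
        path, _ = fixture_bam
        rs = extract_reads_from_bam(path, "chrR:201-205", flank=0)
        names = rs.n_pairs
        assert names >= 1  # the "edge" pair's first read covers base 201 by 1

    def test_missing_index_instructs_to_index(self, fixture_bam, tmp_path):
        import shutil

        path, _ = fixture_bam
        unindexed = tmp_path / "u.bam"
        shutil.copy(path, unindexed)
        with pytest.raises(ValueError, match="index"):
            extract_reads_from_bam(unindexed, "chrR:200-300")

    def test_unknown_chromosome_rejected(self, fixture_bam):
        path, _ = fixture_bam
        with pytest.raises(ValueError, match="absent"):
            extract_reads_from_bam(path, "chrQ:1-100")
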