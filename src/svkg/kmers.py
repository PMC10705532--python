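"""Region-specific k-mer feature index and counting.

The genotyper never aligns reads.  Instead, a fixed, ordered list of
canonical k-mers is harvested from the genotype template haplotypes (wild
type plus each deletion allele of every panel haplotype), subsampled to
every ``stride``-th k-mer to thin out the strong dependence between
overlapping k-mers, and each sample is represented by the vector of counts
of those k-mers in its raw reads.  A separate set of *control* k-mers —
k-mers lying outside every deletable interval and occurring exactly once
per haplotype in every genotype template — provides a depth estimate for
optional per-haploid-copy normalization.

Keys are ordered by first occurrence while scanning the templates
left-to-right in a fixed order, so neighbouring features tend to be
neighbouring loci.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import dna
from .readsim import ReadPairSet
from .region import HaplotypeTemplate
from .variants import ALL_GENOTYPES, Allele, DEFAULT_SVS, SVDefinition, apply_allele

__all__ = [
    "KmerIndex",
    "KmerFeatureVector",
    "genotype_template_sequences",
    "build_kmer_index",
    "count_kmers",
    "normalize",
    "extract_reads_from_bam",
    "save_index",
    "load_index",
]

logger = logging.getLogger(__name__)

_ALLELES_IN_ORDER = (Allele.WT, Allele.DEL37, Allele.DEL42)

_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)


def _prefilter_hash(values: np.ndarray) -> np.ndarray:
    """16-bit multiplicative hash used for the counting prefilter."""
    with np.errstate(over="ignore"):
        return ((values * _HASH_MULT) >> np.uint64(48)).astype(np.int64)


@dataclass(frozen=True)
class KmerIndex:
    k: int
    stride: int
    keys: np.ndarray            # uint64 canonical k-mer values, feature order
    full_positions: np.ndarray  # position of each key in the full ordered list
    n_full: int                 # size of the full deduplicated k-mer list
    control_keys: np.ndarray    # uint64, canonical; single-copy-per-haplotype
    hash: str = ""

    def __post_init__(self):
        if self.hash == "":
            object.__setattr__(self, "hash", self._compute_hash())

    def _compute_hash(self) -> str:
        h = hashlib.sha256()
        h.update(f"k={self.k};stride={self.stride};".encode())
        h.update(np.ascontiguousarray(self.keys).tobytes())
        h.update(b";controls;")
        h.update(np.ascontiguousarray(self.control_keys).tobytes())
        return h.hexdigest()[:16]

    @property
    def n_features(self) -> int:
        return int(self.keys.size)

    def key_strings(self) -> list[str]:
        return [dna.kmer_to_string(int(v), self.k) for v in self.keys]

    # --- counting machinery -------------------------------------------------

    def _lookup(self):
        """Sorted union of keys and control keys, scatter maps back, and a
        one-hash prefilter table for fast counting (cached)."""
        cached = getattr(self, "_lookup_cache", None)
        if cached is None:
            union = np.union1d(self.keys, self.control_keys)
            key_pos = np.searchsorted(union, self.keys)
            ctrl_pos = np.searchsorted(union, self.control_keys)
            table = np.zeros(1 << 16, dtype=bool)
            table[_prefilter_hash(union)] = True
            cached = (union, key_pos, ctrl_pos, table)
            object.__setattr__(self, "_lookup_cache", cached)
        return cached

    def count_values(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Counts of (keys, control_keys) among an array of canonical values."""
        union, key_pos, ctrl_pos, table = self._lookup()
        if union.size == 0:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        # cheap membership prefilter: ~5% false positives, no false negatives
        values = values[table[_prefilter_hash(values)]]
        pos = np.searchsorted(union, values)
        pos[pos == union.size] = 0
        hit = union[pos] == values
        counts_union = np.bincount(pos[hit], minlength=union.size)
        return counts_union[key_pos], counts_union[ctrl_pos]


@dataclass
class KmerFeatureVector:
    """Ordered k-mer counts for one sample, tied to an index by hash."""

    index_hash: str
    counts: np.ndarray
    normalizer: float = 1.0
    sample_id: str = ""
    control_counts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if (self.counts < 0).any():
            raise ValueError("feature counts must be non-negative")


def genotype_template_sequences(
    panel: list[HaplotypeTemplate], svs: dict[str, SVDefinition] | None = None
) -> list[HaplotypeTemplate]:
    """All genotype template haplotypes in fixed order: per panel haplotype,
    the WT, del3.7 and del4.2 alleles."""
    svs = DEFAULT_SVS if svs is None else svs
    out = []
    for t in panel:
        for allele in _ALLELES_IN_ORDER:
            out.append(apply_allele(t, allele, svs))
    return out


def _deletable_spans(template: HaplotypeTemplate, svs: dict[str, SVDefinition]) -> list[tuple[int, int]]:
    """Conservative spans a deletion can disturb: copy-1 start to copy-2 end."""
    spans = []
    for sv in svs.values():
        if sv.box_pair in template.boxes:
            (s1, _e1), (_s2, e2) = template.boxes[sv.box_pair]
            spans.append((s1, e2))
    return spans


def build_kmer_index(
    panel: list[HaplotypeTemplate],
    k: int = 21,
    stride: int = 30,
    svs: dict[str, SVDefinition] | None = None,
    background_fasta=None,
    max_control_keys: int = 2000,
) -> KmerIndex:
    """Build the feature index from a haplotype panel.

    The full list is every canonical k-mer of every genotype template
    haplotype (WT + each deletion allele, fixed template order), deduplicated
    at first occurrence; ``keys`` keeps positions 0, stride, 2*stride, ...
    K-mers containing N are skipped (counted in the log).  ``background_fasta``
    optionally drops keys that also occur in an unrelated background sequence.
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    if k > dna.MAX_K:
        raise ValueError(f"k must be <= {dna.MAX_K}, got {k}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if not panel:
        raise ValueError("template panel must not be empty")
    svs = DEFAULT_SVS if svs is None else svs

    templates = genotype_template_sequences(panel, svs)
    all_vals = []
    n_skipped = 0
    per_template_values = []
    for t in templates:
        vals, skipped = dna.kmer_values(dna.encode(t.sequence), k)
        n_skipped += skipped
        all_vals.append(vals)
        per_template_values.append(vals)
    if n_skipped:
        logger.info("skipped %d k-mers containing non-ACGT bases", n_skipped)

    concat = np.concatenate(all_vals)
    if concat.size == 0:
        raise ValueError("no valid k-mers found in templates")
    uniq, first_idx = np.unique(concat, return_index=True)
    order = np.argsort(first_idx, kind="stable")
    full = uniq[order]  # first-occurrence order

    if background_fasta is not None:
        from Bio import SeqIO

        bg_vals = []
        for rec in SeqIO.parse(str(background_fasta), "fasta"):
            v, _ = dna.kmer_values(dna.encode(str(rec.seq).upper()), k)
            bg_vals.append(v)
        if bg_vals:
            bg = np.unique(np.concatenate(bg_vals))
            keep = ~np.isin(full, bg)
            full = full[keep]

    keys = full[::stride]
    full_positions = np.arange(full.size, dtype=np.int64)[::stride]
    if keys.size == 0:
        raise ValueError("empty key list after subsampling")

    control = _control_keys(panel, per_template_values, k, svs)
    if max_control_keys and control.size > max_control_keys:
        # evenly spaced thinning keeps the depth estimate while keeping the
        # counting lookup table small
        pick = np.linspace(0, control.size - 1, max_control_keys).astype(np.int64)
        control = control[np.unique(pick)]
    return KmerIndex(
        k=k,
        stride=stride,
        keys=keys.copy(),
        full_positions=full_positions.copy(),
        n_full=int(full.size),
        control_keys=control,
    )


def _control_keys(
    panel: list[HaplotypeTemplate],
    per_template_values: list[np.ndarray],
    k: int,
    svs: dict[str, SVDefinition],
) -> np.ndarray:
    """Canonical k-mers outside every deletable span, occurring exactly once
    per haplotype in every genotype template."""
    candidates: np.ndarray | None = None
    for t in panel:
        codes = dna.encode(t.sequence)
        vals, _ = dna.kmer_values(codes, k)
        # positional validity: window [p, p+k) must avoid every deletable span
        keep = np.ones(len(t.sequence) - k + 1, dtype=bool)
        for s, e in _deletable_spans(t, svs):
            lo = max(0, s - k + 1)
            keep[lo:e] = False
        # vals excludes N-windows; N-free synthetic templates keep alignment
        if vals.size != keep.size:
            # N windows present: recompute keep only over valid windows
            valid = np.ones(len(t.sequence) - k + 1, dtype=bool)
            bad = np.cumsum(codes > 3)
            wb = bad[k - 1 :].copy()
            wb[1:] -= bad[: len(t.sequence) - k]
            valid &= wb == 0
            keep = keep[valid]
        safe = np.unique(vals[keep])
        candidates = safe if candidates is None else np.intersect1d(candidates, safe)
    if candidates is None or candidates.size == 0:
        return np.empty(0, np.uint64)

    ok = np.ones(candidates.size, dtype=bool)
    for vals in per_template_values:
        vs, cnt = np.unique(vals, return_counts=True)
        pos = np.searchsorted(vs, candidates)
        pos_c = np.clip(pos, 0, max(vs.size - 1, 0))
        found = (vs.size > 0) & (vs[pos_c] == candidates)
        ok &= found & (cnt[pos_c] == 1)
    return candidates[ok].astype(np.uint64)


# ---------------------------------------------------------------------------
# Counting


def _reads_to_code_stream(reads, k: int) -> np.ndarray:
    """Flatten any supported read container into one code array with 255
    separators between reads; reads shorter than k are skipped and logged."""
    if isinstance(reads, ReadPairSet):
        if reads.ragged is None:
            if reads.n_pairs == 0:
                return np.empty(0, np.uint8)
            rl = reads.r1.shape[1]
            if rl < k:
                logger.warning("all %d reads shorter than k=%d; skipped", 2 * reads.n_pairs, k)
                return np.empty(0, np.uint8)
            n = reads.n_pairs
            block = np.full((2 * n, rl + 1), 255, dtype=np.uint8)
            block[0::2, :rl] = reads.r1
            block[1::2, :rl] = reads.r2
            return block.ravel()
        chunks = reads.all_read_codes()
    elif (
        isinstance(reads, (tuple, list))
        and len(reads) == 2
        and all(isinstance(p, (str, os.PathLike)) and os.path.exists(p) for p in reads)
    ):
        from .readsim import read_fastq_pairs

        chunks = read_fastq_pairs(reads[0], reads[1]).all_read_codes()
    else:
        chunks = [dna.encode(s) for s in reads]

    n_short = sum(1 for c in chunks if c.size < k)
    if n_short:
        logger.warning("skipped %d reads shorter than k=%d", n_short, k)
    return dna.concat_with_separators([c for c in chunks if c.size >= k])


def count_kmers(reads, index: KmerIndex, sample_id: str = "") -> KmerFeatureVector:
    """Count index key occurrences (canonical) across all read sequences.

    ``reads`` may be a :class:`ReadPairSet`, an iterable of sequence strings,
    or a (fastq_r1, fastq_r2) path pair.  The returned vector carries raw
    counts plus a depth normalizer (median control-key count / 2, the
    estimated per-haploid-copy depth), which is only applied by
    :func:`normalize`.
    """
    stream = _reads_to_code_stream(reads, index.k)
    values, _ = dna.kmer_values(stream, index.k)
    counts, control_counts = index.count_values(values)
    if index.control_keys.size:
        normalizer = float(np.median(control_counts)) / 2.0
    else:
        normalizer = 0.0
    return KmerFeatureVector(
        index_hash=index.hash,
        counts=counts.astype(np.float64),
        normalizer=normalizer,
        sample_id=sample_id,
        control_counts=control_counts,
    )


def normalize(vector: KmerFeatureVector, mode: str = "raw") -> KmerFeatureVector:
    """Return the vector unchanged (``raw``) or scaled to per-haploid-copy
    units (``per-haploid-copy``): a k-mer present once per haplotype counts
    about 2.0 in a wild-type diploid."""
    if mode == "raw":
        return replace(vector)
    if mode != "per-haploid-copy":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if vector.normalizer <= 0:
        raise ValueError(
            "normalizer is zero (no control-key coverage); use raw mode or "
            "provide reads with higher coverage"
        )
    return KmerFeatureVector(
        index_hash=vector.index_hash,
        counts=vector.counts / vector.normalizer,
        normalizer=vector.normalizer,
        sample_id=vector.sample_id,
        control_counts=vector.control_counts,
    )


# ---------------------------------------------------------------------------
# BAM extraction


def extract_reads_from_bam(bam_path, region: str, flank: int = 0) -> ReadPairSet:
    """Reads overlapping ``chrom:start-end`` (1-based, inclusive) ± flank,
    plus their placed unmapped mates, re-oriented to original read direction.
    """
    import pysam

    chrom, _, span = region.partition(":")
    try:
        start_s, _, end_s = span.partition("-")
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError as exc:
        raise ValueError(f"malformed region {region!r}; expected chrom:start-end") from exc

    bam = pysam.AlignmentFile(str(bam_path), "rb")
    try:
        if chrom not in bam.references:
            raise ValueError(f"region chromosome {chrom!r} absent from BAM header")
        if not bam.has_index():
            raise ValueError(
                f"{bam_path} has no index; create one with 'samtools index' first"
            )
        lo = max(0, start - 1 - flank)
        hi = end + flank
        mates: dict[str, dict[int, str]] = {}
        for read in bam.fetch(chrom, lo, hi):
            if read.is_secondary or read.is_supplementary or read.query_sequence is None:
                continue
            seq = read.query_sequence
            if read.is_reverse:
                seq = dna.revcomp(seq)
            mate_no = 2 if read.is_read2 else 1
            mates.setdefault(read.query_name, {})[mate_no] = seq
    finally:
        bam.close()

    pairs = []
    for qname in sorted(mates):
        d = mates[qname]
        pairs.append((d.get(1) or d[2], d.get(2) if 1 in d else None))
    return ReadPairSet.from_sequences(pairs, source_id=region)


# ---------------------------------------------------------------------------
# Serialization: TSV of k-mers + JSON header

_FORMAT_VERSION = 1


def save_index(index: KmerIndex, tsv_path, json_path) -> None:
    key_set = set(map(int, index.keys))
    ctrl_set = set(map(int, index.control_keys))
    with open(tsv_path, "w") as fh:
        fh.write("kmer\tfull_position\tis_control\n")
        for value, pos in zip(index.keys, index.full_positions):
            flag = 1 if int(value) in ctrl_set else 0
            fh.write(f"{dna.kmer_to_string(int(value), index.k)}\t{int(pos)}\t{flag}\n")
        for value in index.control_keys:
            if int(value) in key_set:
                continue
            fh.write(f"{dna.kmer_to_string(int(value), index.k)}\t-1\t1\n")
    header = {
        "format_version": _FORMAT_VERSION,
        "k": index.k,
        "stride": index.stride,
        "n_full": index.n_full,
        "hash": index.hash,
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=1)
        fh.write("\n")


def load_index(tsv_path, json_path) -> KmerIndex:
    with open(json_path) as fh:
        header = json.load(fh)
    if header.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"index format version {header.get('format_version')} not supported"
        )
    k = int(header["k"])
    keys, positions, controls = [], [], []
    with open(tsv_path) as fh:
        head = fh.readline().rstrip("\n").split("\t")
        if head != ["kmer", "full_position", "is_control"]:
            raise ValueError(f"unexpected index TSV columns: {head}")
        for line in fh:
            kmer, pos, flag = line.rstrip("\n").split("\t")
            value = dna.string_to_kmer(kmer)
            if int(pos) >= 0:
                keys.append(value)
                positions.append(int(pos))
            if flag == "1":
                controls.append(value)
    index = KmerIndex(
        k=k,
        stride=int(header["stride"]),
        keys=np.array(keys, dtype=np.uint64),
        full_positions=np.array(positions, dtype=np.int64),
        n_full=int(header["n_full"]),
        control_keys=np.array(sorted(controls), dtype=np.uint64),
    )
    if index.hash != header["hash"]:
        raise ValueError(
            "index hash mismatch between TSV content and JSON header "
            f"({index.hash} vs {header['hash']})"
        )
    return index
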