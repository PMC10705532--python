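"""Paired-end short-read simulation from diploid genomes.

Fragments are drawn uniformly along each haplotype (half of the pairs from
each), with lengths from a Normal(insert_mean, insert_sd) truncated to
[read_length, haplotype length] by redrawing, and a uniform per-base
substitution error applied to every read base.  Fragment strand is chosen
with probability 1/2, so read 1 is the 5' read of the sequenced fragment and
read 2 its reverse-complemented 3' read, matching standard Illumina
paired-end geometry.  Base qualities are a constant Phred+33 symbol: the
downstream features are k-mer counts, so the error *rate* matters while the
per-cycle quality profile does not.

The whole simulation is vectorised over reads and deterministic per seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .dna import decode, encode
from .variants import DiploidGenome, GenotypeLabel

__all__ = ["ReadSimParams", "ReadPairSet", "simulate_reads", "write_fastq", "read_fastq_pairs"]

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class ReadSimParams:
    coverage: float = 30.0
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    error_rate: float = 0.002
    quality_char: str = "?"  # Phred+33 Q30
    seed: int = 0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError(f"coverage must be > 0, got {self.coverage}")
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if self.insert_mean < self.read_length:
            raise ValueError(
                "insert_mean must be at least read_length "
                f"(insert_mean={self.insert_mean}, read_length={self.read_length})"
            )
        if self.insert_sd < 0:
            raise ValueError(f"insert_sd must be >= 0, got {self.insert_sd}")
        if len(self.quality_char) != 1 or not 33 <= ord(self.quality_char) <= 126:
            raise ValueError("quality_char must be a single printable Phred+33 symbol")


@dataclass
class ReadPairSet:
    """Paired reads as 2-bit code matrices, plus per-fragment provenance.

    ``r1``/``r2`` are (n_pairs, read_length) uint8 code arrays.  Provenance
    records which haplotype (0 maternal / 1 paternal), fragment start,
    fragment length and strand (0 forward / 1 reverse) each pair came from,
    which lets tests recompute coverage by brute-force pileup.
    """

    r1: np.ndarray
    r2: np.ndarray
    quality_char: str = "?"
    source_id: str = ""
    truth_label: GenotypeLabel | None = None
    haplotype: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    frag_start: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    frag_length: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    strand: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    #: fallback storage for ragged-length reads / missing mates (BAM extraction)
    ragged: list[tuple[str, str | None]] | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.ragged) if self.ragged is not None else self.r1.shape[0]

    def sequences(self):
        """Yield (read1, read2) string pairs; read2 may be None for orphans."""
        if self.ragged is not None:
            yield from self.ragged
            return
        for i in range(self.r1.shape[0]):
            yield decode(self.r1[i]), decode(self.r2[i])

    def all_read_codes(self) -> list[np.ndarray]:
        """All reads (both mates) as a list of code arrays, pair-major order."""
        out = []
        if self.ragged is not None:
            for a, b in self.ragged:
                out.append(encode(a))
                if b is not None:
                    out.append(encode(b))
            return out
        for i in range(self.r1.shape[0]):
            out.append(self.r1[i])
            out.append(self.r2[i])
        return out

    @classmethod
    def from_sequences(cls, pairs, source_id: str = "", quality_char: str = "?"):
        """Build from (read1, read2) string pairs; read2 may be None."""
        pairs = [(a, b) for a, b in pairs]
        empty = np.empty((0, 0), np.uint8)
        if not pairs:
            return cls(r1=empty, r2=empty, source_id=source_id, quality_char=quality_char)
        lengths = {len(a) for a, _ in pairs} | {len(b) for _, b in pairs if b is not None}
        if len(lengths) == 1 and all(b is not None for _, b in pairs):
            r1 = np.stack([encode(a) for a, _ in pairs])
            r2 = np.stack([encode(b) for _, b in pairs])
            return cls(r1=r1, r2=r2, source_id=source_id, quality_char=quality_char)
        return cls(
            r1=empty, r2=empty, source_id=source_id, quality_char=quality_char, ragged=pairs
        )


def _truncated_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    """Normal(mean, sd) rounded to int, truncated to [lo, hi] by redrawing."""
    if lo > hi:
        raise ValueError("haplotype shorter than read_length")
    out = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    for _ in range(_MAX_REDRAWS):
        bad = (out < lo) | (out > hi)
        n_bad = int(bad.sum())
        if not n_bad:
            return out
        out[bad] = np.rint(rng.normal(mean, sd, size=n_bad)).astype(np.int64)
    # pathological parameters (e.g. mean far outside [lo, hi]); clamp remainder
    return np.clip(out, lo, hi)


def _apply_errors(rng: np.random.Generator, reads: np.ndarray, rate: float) -> None:
    if rate <= 0:
        return
    hit = rng.random(reads.shape) < rate
    n = int(hit.sum())
    if n:
        reads[hit] = (reads[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) & 3


def simulate_reads(genome: DiploidGenome, params: ReadSimParams) -> ReadPairSet:
    """Simulate a paired-end read set from a diploid genome.

    The number of pairs is ``round(coverage * mean haplotype length /
    (2 * read_length))``, i.e. fold coverage counts sequenced read bases per
    haploid position.  Pairs are split evenly between the two haplotypes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rl = params.read_length

    haps = [encode(genome.maternal), encode(genome.paternal)]
    min_len = params.insert_mean + 4 * params.insert_sd
    for name, h in zip(("maternal", "paternal"), haps):
        if h.size <= min_len:
            raise ValueError(
                f"{name} haplotype (length {h.size}) must be longer than "
                f"insert_mean + 4*insert_sd = {min_len:.0f}"
            )

    n_pairs = int(round(params.coverage * genome.mean_length / (2 * rl)))
    n_per_hap = [(n_pairs + 1) // 2, n_pairs // 2]

    r1_parts, r2_parts = [], []
    hap_idx, starts_all, lengths_all, strands_all = [], [], [], []
    offsets = np.arange(rl)
    for hi, (hap, n_h) in enumerate(zip(haps, n_per_hap)):
        if n_h == 0:
            continue
        L = hap.size
        flen = _truncated_lengths(rng, n_h, params.insert_mean, params.insert_sd, rl, L)
        starts = np.floor(rng.random(n_h) * (L - flen + 1)).astype(np.int64)
        strand = (rng.random(n_h) < 0.5).astype(np.int8)  # 1 = fragment on reverse strand

        head = hap[starts[:, None] + offsets[None, :]]
        tail_rc = (3 - hap[(starts + flen - 1)[:, None] - offsets[None, :]]) & 3
        rev = strand.astype(bool)
        r1 = np.where(rev[:, None], tail_rc, head)
        r2 = np.where(rev[:, None], head, tail_rc)
        _apply_errors(rng, r1, params.error_rate)
        _apply_errors(rng, r2, params.error_rate)

        r1_parts.append(r1)
        r2_parts.append(r2)
        hap_idx.append(np.full(n_h, hi, np.int8))
        starts_all.append(starts)
        lengths_all.append(flen)
        strands_all.append(strand)

    empty = np.empty((0, rl), np.uint8)
    return ReadPairSet(
        r1=np.concatenate(r1_parts) if r1_parts else empty,
        r2=np.concatenate(r2_parts) if r2_parts else empty,
        quality_char=params.quality_char,
        source_id=genome.id,
        truth_label=genome.label,
        haplotype=np.concatenate(hap_idx) if hap_idx else np.empty(0, np.int8),
        frag_start=np.concatenate(starts_all) if starts_all else np.empty(0, np.int64),
        frag_length=np.concatenate(lengths_all) if lengths_all else np.empty(0, np.int64),
        strand=np.concatenate(strands_all) if strands_all else np.empty(0, np.int8),
    )


def _open_maybe_gz(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(pairs: ReadPairSet, path_r1, path_r2) -> None:
    """Write mates to two FASTQ files; ids share a stem with /1 and /2 suffixes."""
    stem = pairs.source_id or "read"
    q = pairs.quality_char
    with _open_maybe_gz(path_r1) as f1, _open_maybe_gz(path_r2) as f2:
        for i, (s1, s2) in enumerate(pairs.sequences()):
            if s2 is None:
                raise ValueError("cannot write orphan reads as paired FASTQ")
            f1.write(f"@{stem}:{i}/1\n{s1}\n+\n{q * len(s1)}\n")
            f2.write(f"@{stem}:{i}/2\n{s2}\n+\n{q * len(s2)}\n")


def read_fastq_pairs(path_r1, path_r2, source_id: str = "") -> ReadPairSet:
    """Read two mate FASTQ files back into a ReadPairSet."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    def _read(path):
        with _open_maybe_gz(path, "rt") as fh:
            return [seq for _, seq, _ in FastqGeneralIterator(fh)]

    s1, s2 = _read(path_r1), _read(path_r2)
    if len(s1) != len(s2):
        raise ValueError(f"mate files differ in read count: {len(s1)} vs {len(s2)}")
    return ReadPairSet.from_sequences(zip(s1, s2), source_id=source_id)
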