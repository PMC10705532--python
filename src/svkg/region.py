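"""Synthetic haplotype panels emulating the human alpha-globin locus.

The alpha-globin genes sit inside two tandem, highly identical ~4 kb
duplication units ("cassettes") on 16p13.3.  Non-allelic homologous
recombination between repeat pairs embedded in the cassettes produces the
common thalassemia deletions: the Z-box pair mediates the ~3.8 kb rightward
deletion and the X-box pair the ~4.2 kb leftward deletion.  Because real
pangenome haplotypes cannot be redistributed here, :func:`generate_haplotype_panel`
builds a panel of synthetic haplotypes that reproduces the features the
genotyping method depends on: tandem cassettes at high identity, nearly
identical box repeats at the locus-appropriate spacings, and SNP-level
diversity between haplotypes.

Coordinates are 0-based, half-open, forward strand throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import decode, encode

__all__ = [
    "BoxSpec",
    "CassetteSpec",
    "RegionBlueprint",
    "HaplotypeTemplate",
    "BlueprintError",
    "generate_haplotype_panel",
    "default_blueprint",
    "save_panel",
    "load_haplotypes",
]


class BlueprintError(ValueError):
    """Raised when a blueprint's geometry or rates are invalid."""


@dataclass(frozen=True)
class BoxSpec:
    """A pair of homologous repeat copies planted into the region.

    ``positions`` are the start offsets of the two copies; ``divergence`` is
    the per-base substitution probability between the copies (copy 1 is
    derived from copy 2's ancestral content).  Copies must stay >= 95%
    identical by default, mirroring the near-perfect homology that lets
    recombination confuse them.
    """

    name: str
    length: int
    positions: tuple[int, int]
    divergence: float = 0.0


@dataclass(frozen=True)
class CassetteSpec:
    """A tandem duplication unit: copy 2 is copy 1 resampled at ``divergence``.

    ``pseudo_start`` optionally places a third, decayed paralog of the
    cassette (a pseudogene copy, resampled at the higher
    ``pseudo_divergence``) elsewhere in the region.  It takes part in no
    deletion but shares most k-mers with the functional copies, which
    weakens pure depth contrasts the way paralogs do at the real locus.
    """

    start1: int
    start2: int
    length: int
    divergence: float = 0.0
    pseudo_start: int | None = None
    pseudo_divergence: float = 0.02


@dataclass(frozen=True)
class RegionBlueprint:
    region_length: int = 40_000
    # Two identical 3.9 kb gene cassettes; the X boxes flank the second
    # copy exactly, so the "leftward" ~4.2 kb deletion removes one
    # cassette's worth of purely duplicated sequence — a pure copy-number
    # change, detectable only through read depth.  The first copy sits
    # upstream of both deletion spans and provides the surviving reference
    # copy of that content whatever the other haplotype carries.
    # A decayed pseudogene paralog of the cassette sits further upstream;
    # it takes part in no deletion but shares most cassette k-mers, which
    # further flattens the depth contrast of the leftward deletion.
    cassette: CassetteSpec = field(
        default_factory=lambda: CassetteSpec(
            start1=8_000, start2=12_900, length=3_900, divergence=0.0,
            pseudo_start=3_000, pseudo_divergence=0.02,
        )
    )
    # X boxes sit upstream of Z boxes, so the ~4.2 kb leftward deletion
    # lies 5' of the ~3.8 kb rightward one and the intervals only partially
    # overlap.  X copies are identical (no junction signal); Z copies carry
    # ~3% paralogous variants, and the rightward deletion span crosses into
    # single-copy downstream sequence, so it removes unique and Z-specific
    # k-mers and creates hybrid-junction k-mers.
    box_specs: tuple[BoxSpec, ...] = field(
        default_factory=lambda: (
            BoxSpec("Z", 300, (16_300, 20_100), divergence=0.03),
            BoxSpec("X", 300, (12_600, 16_800), divergence=0.0),
        )
    )
    snp_rate: float = 0.001
    n_haplotypes: int = 14
    seed: int = 1
    max_box_divergence: float = 0.05

    def validate(self) -> None:
        if self.region_length < 2 * self.cassette.length:
            raise BlueprintError(
                "region_length must be at least twice cassette_length "
                f"(region_length={self.region_length}, cassette length={self.cassette.length})"
            )
        if self.n_haplotypes < 2:
            raise BlueprintError(f"n_haplotypes must be >= 2, got {self.n_haplotypes}")
        if not 0.0 <= self.snp_rate < 1.0:
            raise BlueprintError(f"snp_rate must be in [0, 1), got {self.snp_rate}")
        c = self.cassette
        if c.start2 < c.start1 + c.length:
            raise BlueprintError("cassette: copies overlap (start2 < start1 + length)")
        if c.start2 + c.length > self.region_length:
            raise BlueprintError("cassette: copy 2 extends past region_length")
        if c.pseudo_start is not None:
            p0, p1 = c.pseudo_start, c.pseudo_start + c.length
            if p0 < 0 or p1 > self.region_length:
                raise BlueprintError("cassette: pseudogene copy outside region_length")
            if p1 > c.start1 and p0 < c.start2 + c.length:
                raise BlueprintError("cassette: pseudogene copy overlaps a functional copy")
        if not self.box_specs:
            raise BlueprintError("box_specs must not be empty")
        for box in self.box_specs:
            if box.length < 1:
                raise BlueprintError(f"box_specs[{box.name}]: length must be positive")
            p1, p2 = box.positions
            if p2 < p1 + box.length:
                raise BlueprintError(f"box_specs[{box.name}]: copies overlap")
            if p1 < 0 or p2 + box.length > self.region_length:
                raise BlueprintError(
                    f"box_specs[{box.name}]: copy coordinates fall outside region_length"
                )
            if not 0.0 <= box.divergence <= self.max_box_divergence:
                raise BlueprintError(
                    f"box_specs[{box.name}]: inter-copy divergence {box.divergence} outside "
                    f"[0, {self.max_box_divergence}] (copies must stay >=95% identical)"
                )


@dataclass
class HaplotypeTemplate:
    """One haplotype of the region, with its homologous box pair annotations.

    ``boxes`` maps a box-pair name to two 0-based half-open intervals of
    equal length, with the first ending before the second starts.
    """

    id: str
    sequence: str
    boxes: dict[str, tuple[tuple[int, int], tuple[int, int]]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"template {self.id}: sequence contains characters outside A/C/G/T/N: {sorted(bad)}"
            )
        n = len(self.sequence)
        for name, ((s1, e1), (s2, e2)) in self.boxes.items():
            if e1 - s1 != e2 - s2:
                raise ValueError(f"template {self.id}, box {name}: copies have unequal length")
            if not (0 <= s1 < e1 <= s2 < e2 <= n):
                raise ValueError(
                    f"template {self.id}, box {name}: intervals must be ordered, "
                    f"non-overlapping and within the sequence (length {n})"
                )
            if "N" in self.sequence[s1:e1] or "N" in self.sequence[s2:e2]:
                raise ValueError(
                    f"template {self.id}, box {name}: N bases inside a box interval are not allowed"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def box_identity(self, name: str) -> float:
        """Fraction of identical positions between the two copies of a box pair."""
        (s1, e1), (s2, e2) = self.boxes[name]
        a = np.frombuffer(self.sequence[s1:e1].encode(), dtype=np.uint8)
        b = np.frombuffer(self.sequence[s2:e2].encode(), dtype=np.uint8)
        return float((a == b).mean())


def default_blueprint(**overrides) -> RegionBlueprint:
    """The stock alpha-globin-like blueprint, with optional field overrides."""
    return dataclasses.replace(RegionBlueprint(), **overrides)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = rng.random(out.size) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) & 3
    return out


def generate_haplotype_panel(blueprint: RegionBlueprint) -> list[HaplotypeTemplate]:
    """Generate ``n_haplotypes`` templates sharing one repeat architecture.

    A common ancestor sequence is drawn uniformly at random, the cassette
    duplication and box homologies are stamped in, and each haplotype is then
    the ancestor plus i.i.d. substitutions at ``snp_rate`` per site.  All
    haplotypes therefore share box coordinates exactly (no indel variation
    between haplotypes).  Deterministic for a given blueprint and seed.
    """
    blueprint.validate()
    rng = np.random.default_rng(blueprint.seed)

    ancestor = rng.integers(0, 4, size=blueprint.region_length, dtype=np.uint8)
    c = blueprint.cassette
    ancestor[c.start2 : c.start2 + c.length] = _mutate(
        rng, ancestor[c.start1 : c.start1 + c.length], c.divergence
    )
    if c.pseudo_start is not None:
        ancestor[c.pseudo_start : c.pseudo_start + c.length] = _mutate(
            rng, ancestor[c.start1 : c.start1 + c.length], c.pseudo_divergence
        )
    # boxes are stamped after the cassette copies, copy 2 -> copy 1, so a
    # box pair's divergent variants stay private to the pair instead of
    # propagating into the paralog copies
    for box in blueprint.box_specs:
        p1, p2 = box.positions
        ancestor[p1 : p1 + box.length] = _mutate(
            rng, ancestor[p2 : p2 + box.length], box.divergence
        )

    boxes = {
        box.name: ((box.positions[0], box.positions[0] + box.length),
                   (box.positions[1], box.positions[1] + box.length))
        for box in blueprint.box_specs
    }
    width = len(str(blueprint.n_haplotypes))
    panel = []
    for i in range(blueprint.n_haplotypes):
        hap = _mutate(rng, ancestor, blueprint.snp_rate)
        panel.append(
            HaplotypeTemplate(
                id=f"hap{i + 1:0{width}d}",
                sequence=decode(hap),
                boxes=dict(boxes),
                source="synthetic",
            )
        )
    return panel


# ---------------------------------------------------------------------------
# FASTA + box-table serialization

_BOX_COLUMNS = ["record_id", "box_name", "copy_index", "start", "end"]


def save_panel(panel: list[HaplotypeTemplate], fasta_path, box_table_path) -> None:
    """Write templates as FASTA plus a TSV of box intervals (0-based half-open)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in panel
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(box_table_path, "w") as fh:
        fh.write("\t".join(_BOX_COLUMNS) + "\n")
        for t in panel:
            for name, intervals in sorted(t.boxes.items()):
                for copy_index, (start, end) in enumerate(intervals, start=1):
                    fh.write(f"{t.id}\t{name}\t{copy_index}\t{start}\t{end}\n")


def load_haplotypes(fasta_path, box_table_path) -> list[HaplotypeTemplate]:
    """Load templates from FASTA plus a box TSV; intervals are validated.

    Every FASTA record must have at least one box entry; each box pair needs
    copy_index 1 and 2.  N bases are tolerated in the sequence but rejected
    inside box intervals (they would make junction k-mers ambiguous).
    """
    table: dict[str, dict[str, dict[int, tuple[int, int]]]] = {}
    with open(box_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _BOX_COLUMNS:
            raise ValueError(
                f"box table {box_table_path}: expected columns {_BOX_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"box table line {lineno}: expected 5 fields")
            rec, name, copy_index, start, end = fields
            table.setdefault(rec, {}).setdefault(name, {})[int(copy_index)] = (
                int(start),
                int(end),
            )

    panel = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if record.id not in table:
            raise ValueError(f"box table has no entries for FASTA record {record.id!r}")
        boxes = {}
        for name, copies in table[record.id].items():
            if set(copies) != {1, 2}:
                raise ValueError(
                    f"record {record.id}, box {name}: need copy_index 1 and 2, got {sorted(copies)}"
                )
            for _, (start, end) in sorted(copies.items()):
                if not (0 <= start < end <= len(seq)):
                    raise ValueError(
                        f"record {record.id}, box {name}: interval [{start}, {end}) "
                        f"outside sequence of length {len(seq)}"
                    )
            boxes[name] = (copies[1], copies[2])
        panel.append(HaplotypeTemplate(id=record.id, sequence=seq, boxes=boxes, source="file"))
    if not panel:
        raise ValueError(f"no records found in {fasta_path}")
    return panel


def pairwise_divergence(a: HaplotypeTemplate, b: HaplotypeTemplate) -> float:
    """Hamming distance / length between two equal-length templates."""
    if len(a) != len(b):
        raise ValueError("templates differ in length")
    ca, cb = encode(a.sequence), encode(b.sequence)
    return float((ca != cb).mean())
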