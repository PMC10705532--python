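"""Homologous-recombination deletions and diploid genotype panels.

A deletion is defined by a pair of homologous boxes: recombination between
copy 1 and copy 2 removes exactly ``start(copy2) - start(copy1)`` bases and
leaves a single hybrid box whose 5' side comes from copy 1 and whose 3' side
comes from copy 2.  With the default alpha-globin-like blueprint this yields
the ~3.8 kb rightward ("del3.7", Z boxes) and ~4.2 kb leftward ("del4.2",
X boxes) deletions.

Diploid genotypes combine alleles from {WT, DEL37, DEL42}; exactly six
unordered genotype classes exist.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .region import HaplotypeTemplate

__all__ = [
    "Allele",
    "GenotypeLabel",
    "ALL_GENOTYPES",
    "SVDefinition",
    "SVDefinitionError",
    "DiploidGenome",
    "DEFAULT_SVS",
    "apply_deletion",
    "apply_allele",
    "build_genotype_panel",
    "write_diploid_fasta",
    "load_sv_definitions",
]


class Allele(str, enum.Enum):
    WT = "WT"
    DEL37 = "DEL37"
    DEL42 = "DEL42"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_ALLELE_ORDER = {Allele.WT: 0, Allele.DEL37: 1, Allele.DEL42: 2}


@dataclass(frozen=True, order=True)
class GenotypeLabel:
    """An unordered diploid genotype over {WT, DEL37, DEL42}; order-normalized."""

    allele1: Allele
    allele2: Allele

    def __post_init__(self):
        a, b = self.allele1, self.allele2
        if _ALLELE_ORDER[a] > _ALLELE_ORDER[b]:
            object.__setattr__(self, "allele1", b)
            object.__setattr__(self, "allele2", a)

    @property
    def alleles(self) -> tuple[Allele, Allele]:
        return (self.allele1, self.allele2)

    def __str__(self) -> str:
        return f"{self.allele1.value}/{self.allele2.value}"

    @classmethod
    def from_string(cls, text: str) -> "GenotypeLabel":
        a, _, b = text.partition("/")
        return cls(Allele(a), Allele(b))


#: Fixed class order used everywhere a class axis is needed (WT/WT first).
ALL_GENOTYPES: tuple[GenotypeLabel, ...] = (
    GenotypeLabel(Allele.WT, Allele.WT),
    GenotypeLabel(Allele.WT, Allele.DEL37),
    GenotypeLabel(Allele.WT, Allele.DEL42),
    GenotypeLabel(Allele.DEL37, Allele.DEL37),
    GenotypeLabel(Allele.DEL37, Allele.DEL42),
    GenotypeLabel(Allele.DEL42, Allele.DEL42),
)


class SVDefinitionError(ValueError):
    """Raised for malformed SV definitions or definitions a template lacks."""


@dataclass(frozen=True)
class SVDefinition:
    """A deletion mediated by recombination between two homologous box copies.

    ``breakpoint_offset`` places the hybrid junction within the box; any
    value in [0, box length] yields the same deletion size (the genotype-
    discriminating quantity), so by default the midpoint is used.
    """

    name: str
    box_pair: str
    breakpoint_offset: int | None = None

    def offset_for(self, box_length: int) -> int:
        off = box_length // 2 if self.breakpoint_offset is None else self.breakpoint_offset
        if not 0 <= off <= box_length:
            raise SVDefinitionError(
                f"SV {self.name}: breakpoint_offset {off} outside [0, {box_length}]"
            )
        return off

    def deleted_interval(self, template: HaplotypeTemplate) -> tuple[int, int]:
        if self.box_pair not in template.boxes:
            raise SVDefinitionError(
                f"SV {self.name}: template {template.id} has no box pair {self.box_pair!r}"
            )
        (s1, e1), (s2, _e2) = template.boxes[self.box_pair]
        off = self.offset_for(e1 - s1)
        return (s1 + off, s2 + off)


DEFAULT_SVS: dict[str, SVDefinition] = {
    "del3.7": SVDefinition("del3.7", box_pair="Z"),
    "del4.2": SVDefinition("del4.2", box_pair="X"),
}

_ALLELE_TO_SV = {Allele.DEL37: "del3.7", Allele.DEL42: "del4.2"}


def apply_deletion(template: HaplotypeTemplate, sv: SVDefinition) -> HaplotypeTemplate:
    """Collapse a box pair, removing ``start(copy2) - start(copy1)`` bases.

    The returned haplotype keeps only box pairs whose copies both survive
    intact and still flank each other; the collapsed pair itself is dropped,
    so applying the same deletion twice raises.
    """
    cut_start, cut_end = sv.deleted_interval(template)
    (s1, _), (s2, _) = template.boxes[sv.box_pair]
    removed = cut_end - cut_start
    assert removed == s2 - s1
    new_seq = template.sequence[:cut_start] + template.sequence[cut_end:]

    def shift(pos: int) -> int:
        return pos if pos < cut_start else pos - removed

    new_boxes = {}
    for name, ((bs1, be1), (bs2, be2)) in template.boxes.items():
        if name == sv.box_pair:
            continue  # collapsed to a single hybrid copy
        intact = all(
            be <= cut_start or bs >= cut_end for bs, be in ((bs1, be1), (bs2, be2))
        )
        if not intact:
            continue  # a copy was (partially) removed; pair no longer exists
        new_boxes[name] = ((shift(bs1), shift(be1)), (shift(bs2), shift(be2)))

    return HaplotypeTemplate(
        id=f"{template.id}.{sv.name}",
        sequence=new_seq,
        boxes=new_boxes,
        source=template.source,
    )


def apply_allele(
    template: HaplotypeTemplate, allele: Allele, svs: dict[str, SVDefinition] | None = None
) -> HaplotypeTemplate:
    """Template sequence for one allele: unchanged for WT, deleted otherwise."""
    if allele is Allele.WT:
        return template
    svs = DEFAULT_SVS if svs is None else svs
    sv_name = _ALLELE_TO_SV[allele]
    if sv_name not in svs:
        raise SVDefinitionError(f"no SV definition named {sv_name!r} provided")
    return apply_deletion(template, svs[sv_name])


@dataclass
class DiploidGenome:
    """Two haplotype sequences plus the genotype that produced them."""

    maternal: str
    paternal: str
    label: GenotypeLabel
    template_ids: tuple[str, str]

    @property
    def id(self) -> str:
        return f"{self.template_ids[0]}x{self.template_ids[1]}.{self.label}".replace("/", "_")

    @property
    def mean_length(self) -> float:
        return (len(self.maternal) + len(self.paternal)) / 2.0


def build_genotype_panel(
    templates: list[HaplotypeTemplate],
    svs: dict[str, SVDefinition] | None = None,
    pairing: str | list[tuple[int, int]] = "all-ordered-pairs",
) -> list[DiploidGenome]:
    """All (template pair, genotype) diploid genomes in deterministic order.

    With ``pairing="all-ordered-pairs"`` and n templates this yields
    n x n pairs x 6 genotypes (7 maternal x 7 paternal choices reproduce the
    49 haplotype combinations x 6 genotypes = 294 genomes of the training
    design).  ``pairing`` may instead be an explicit list of (maternal_index,
    paternal_index) tuples.
    """
    if not templates:
        raise ValueError("template list must not be empty")
    svs = DEFAULT_SVS if svs is None else svs
    for required in ("del3.7", "del4.2"):
        if required not in svs:
            raise SVDefinitionError(f"SV definition {required!r} is required")
    if pairing == "all-ordered-pairs":
        pairs = list(itertools.product(range(len(templates)), repeat=2))
    elif pairing == "all-unordered-pairs":
        pairs = list(itertools.combinations_with_replacement(range(len(templates)), 2))
    else:
        pairs = list(pairing)

    allele_cache: dict[tuple[int, Allele], str] = {}

    def hap_seq(idx: int, allele: Allele) -> str:
        key = (idx, allele)
        if key not in allele_cache:
            allele_cache[key] = apply_allele(templates[idx], allele, svs).sequence
        return allele_cache[key]

    genomes = []
    for mi, pi in pairs:
        for label in ALL_GENOTYPES:
            genomes.append(
                DiploidGenome(
                    maternal=hap_seq(mi, label.allele1),
                    paternal=hap_seq(pi, label.allele2),
                    label=label,
                    template_ids=(templates[mi].id, templates[pi].id),
                )
            )
    return genomes


def write_diploid_fasta(genome: DiploidGenome, path) -> None:
    """Write a two-record FASTA; ids encode template, allele and genotype."""
    label = str(genome.label).replace("/", "_")
    records = [
        SeqRecord(
            Seq(genome.maternal),
            id=f"{genome.template_ids[0]}.maternal.{genome.label.allele1.value}.{label}",
            description="",
        ),
        SeqRecord(
            Seq(genome.paternal),
            id=f"{genome.template_ids[1]}.paternal.{genome.label.allele2.value}.{label}",
            description="",
        ),
    ]
    SeqIO.write(records, str(path), "fasta")


def load_sv_definitions(path) -> dict[str, SVDefinition]:
    """Read SV definitions from YAML: a list of {name, box_pair, breakpoint_offset}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise SVDefinitionError("SV definition file must contain a list of mappings")
    out = {}
    for entry in raw:
        try:
            sv = SVDefinition(
                name=entry["name"],
                box_pair=entry["box_pair"],
                breakpoint_offset=entry.get("breakpoint_offset"),
            )
        except (KeyError, TypeError) as exc:
            raise SVDefinitionError(f"malformed SV definition entry {entry!r}") from exc
        out[sv.name] = sv
    return out


def deletion_size(template: HaplotypeTemplate, sv: SVDefinition) -> int:
    """Number of bases the deletion removes on this template."""
    (s1, _), (s2, _) = template.boxes[sv.box_pair]
    return s2 - s1
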