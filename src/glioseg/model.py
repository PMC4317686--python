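"""Core domain types for familial rare-variant co-segregation analysis.

The objects here model a multi-family cohort sequenced over a targeted
genomic region: pedigrees with affected/sequenced flags, annotated variant
calls with population frequencies and CADD scaled C-scores, per-individual
genotype calls, and the per-family carrier-ratio records produced at the
end of the triage.

Coordinates are 1-based inclusive throughout (VCF convention); BED input
is converted on read. Population frequencies are stored in percent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional


class GenotypeCall(enum.Enum):
    """Diploid call of an individual for one alternate allele."""

    CARRIER_HET = "carrier-het"
    CARRIER_HOM = "carrier-hom"
    NON_CARRIER = "non-carrier"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        # het and hom alternate both count as carriers; the triage never
        # distinguishes zygosity
        return self in (GenotypeCall.CARRIER_HET, GenotypeCall.CARRIER_HOM)


class FunctionalClass(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    UTR = "UTR"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER_NONCODING = "other-noncoding"


#: Classes that change the protein product.
PROTEIN_ALTERING: frozenset[FunctionalClass] = frozenset(
    {
        FunctionalClass.MISSENSE,
        FunctionalClass.NONSENSE,
        FunctionalClass.FRAMESHIFT,
        FunctionalClass.SPLICE,
    }
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed interval on one chromosome, 1-based inclusive endpoints."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance_to(self, pos: int) -> int:
        """Gap in bases between ``pos`` and the interval; 0 if inside."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TargetInterval(GenomicInterval):
    """A capture-design target; ``exonic`` marks coding-exon targets."""

    exonic: bool = False


# the two chr17q intervals of the 1.7-LOD-drop linkage region (GRCh37)
DEFAULT_LINKAGE_INTERVALS: tuple[GenomicInterval, ...] = (
    GenomicInterval("17", 34_355_567, 52_135_011),
    GenomicInterval("17", 54_612_056, 61_596_548),
)


@dataclass(frozen=True)
class LinkageLocus:
    """An ordered, non-overlapping set of linkage-region intervals."""

    intervals: tuple[GenomicInterval, ...] = DEFAULT_LINKAGE_INTERVALS

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"linkage intervals overlap or are unsorted: {a}, {b}"
                    )

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return any(iv.chrom == chrom and pos in iv for iv in self.intervals)


@dataclass(frozen=True)
class PopulationFrequencies:
    """Reference-database allele frequencies, in percent.

    ``None`` means the variant is absent from (or unreported in) that
    database — a missing frequency never triggers a rarity-filter drop.
    """

    esp_percent: Optional[float] = None
    kg_percent: Optional[float] = None
    kg_ceu_percent: Optional[float] = None
    esp_release: str = "ESP6500"
    kg_release: str = "1000G 2012_04"
    kg_ceu_release: str = "1000G 2010_07"

    def __post_init__(self) -> None:
        for name in ("esp_percent", "kg_percent", "kg_ceu_percent"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100] percent")

    def get(self, which: str) -> Optional[float]:
        return {
            "esp": self.esp_percent,
            "kg": self.kg_percent,
            "kg_ceu": self.kg_ceu_percent,
        }[which]

    @property
    def all_absent(self) -> bool:
        return (
            self.esp_percent is None
            and self.kg_percent is None
            and self.kg_ceu_percent is None
        )


VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele with its functional and frequency annotation."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_symbol: Optional[str] = None
    functional_class: FunctionalClass = FunctionalClass.OTHER_NONCODING
    dbsnp_id: Optional[str] = None
    freqs: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    scaled_c_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        if self.scaled_c_score is not None and self.scaled_c_score < 0:
            raise ValueError("scaled_c_score must be >= 0")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"  # "male" | "female" | "unknown"
    affected: bool = False
    sequenced: bool = False
    age_at_diagnosis: Optional[float] = None
    histology: Optional[str] = None


@dataclass
class Family:
    family_id: str
    members: list[Individual]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id} has no members")
        ids = [m.individual_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate individual id in family {self.family_id}")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise ValueError(
                        f"individual {m.individual_id} in family {self.family_id} "
                        f"references unknown parent {pid!r}"
                    )

    def __iter__(self):
        return iter(self.members)

    def get(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def sequenced_affected(self) -> list[Individual]:
        return [m for m in self.members if m.sequenced and m.affected]

    @property
    def sequenced_unaffected(self) -> list[Individual]:
        return [m for m in self.members if m.sequenced and not m.affected]


@dataclass
class Cohort:
    """Families, variants, and the genotype map joining them.

    ``genotypes`` is keyed by (variant key, individual id) and contains
    entries for sequenced individuals only; unsequenced members have no
    genotype entries.
    """

    families: list[Family]
    variants: list[AnnotatedVariant] = field(default_factory=list)
    genotypes: dict[tuple[VariantKey, str], GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        keys = {v.key for v in self.variants}
        seq: dict[str, Individual] = {}
        for fam in self.families:
            for m in fam.members:
                if m.sequenced:
                    seq[m.individual_id] = m
        for (vkey, iid) in self.genotypes:
            if vkey not in keys:
                raise ValueError(f"genotype entry for unknown variant {vkey}")
            if iid not in seq:
                raise ValueError(
                    f"genotype entry for unsequenced or unknown individual {iid!r}"
                )

    def family(self, family_id: str) -> Family:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)

    def call(self, variant: AnnotatedVariant, individual_id: str) -> GenotypeCall:
        """Genotype call, MISSING if the individual has no entry."""
        return self.genotypes.get((variant.key, individual_id), GenotypeCall.MISSING)

    def is_carrier(self, variant: AnnotatedVariant, individual_id: str) -> bool:
        return self.call(variant, individual_id).is_carrier

    def carriers(self, variant: AnnotatedVariant, members: Iterable[Individual]) -> list[Individual]:
        return [m for m in members if self.is_carrier(variant, m.individual_id)]

    @property
    def sequenced_individuals(self) -> list[Individual]:
        return [m for fam in self.families for m in fam.members if m.sequenced]


@dataclass(frozen=True)
class CandidateRecord:
    """Per-family carrier ratios for one final-list candidate variant.

    Numerators count carriers among sequenced members of the stratum;
    denominators count all sequenced members of the stratum.
    """

    family_id: str
    variant: AnnotatedVariant
    affected_carriers: int
    affected_sequenced: int
    unaffected_carriers: int
    unaffected_sequenced: int

    def __post_init__(self) -> None:
        if not (0 <= self.affected_carriers <= self.affected_sequenced):
            raise ValueError("affected carrier count outside [0, sequenced]")
        if not (0 <= self.unaffected_carriers <= self.unaffected_sequenced):
            raise ValueError("unaffected carrier count outside [0, sequenced]")

    @property
    def affected_ratio(self) -> str:
        return f"{self.affected_carriers}/{self.affected_sequenced}"

    @property
    def unaffected_ratio(self) -> str:
        return f"{self.unaffected_carriers}/{self.unaffected_sequenced}"
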