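"""Carrier ratios, sharing/novelty/privacy classification, multi-family genes.

These operations summarise the final candidate list the way familial
rare-variant studies report it: per-family carrier ratios among sequenced
affected and unaffected relatives, whether a candidate co-segregates in
two or more affected relatives or rests on a single sequenced affected,
whether it is novel (absent from dbSNP, ESP and 1000 Genomes), private to
one family, and which genes are implicated by more than one family.

Unaffected carrier ratios are reported but never filtered on: incomplete
penetrance is expected for a low-penetrance predisposition allele.
"""

from __future__ import annotations

import enum
from typing import Iterable, Sequence

from .model import AnnotatedVariant, CandidateRecord, Cohort, Family


class SharingClass(enum.Enum):
    """Final-list candidates split by affected-carrier support."""

    SHARED = "shared"  # >= 2 sequenced affected, all carriers
    SINGLE_AFFECTED = "single_affected"  # family has exactly 1 sequenced affected


def carrier_ratios(
    variant: AnnotatedVariant, family: Family, cohort: Cohort
) -> CandidateRecord:
    """Affected and unaffected carrier ratios of ``variant`` in ``family``.

    Numerators count carrier genotype calls among sequenced members of the
    stratum; a missing genotype counts as non-carrier in the numerator but
    the individual stays in the denominator.
    """
    affected = family.sequenced_affected
    unaffected = family.sequenced_unaffected
    return CandidateRecord(
        family_id=family.family_id,
        variant=variant,
        affected_carriers=len(cohort.carriers(variant, affected)),
        affected_sequenced=len(affected),
        unaffected_carriers=len(cohort.carriers(variant, unaffected)),
        unaffected_sequenced=len(unaffected),
    )


def classify_sharing(record: CandidateRecord) -> SharingClass:
    """Shared (>= 2 co-segregating affected) vs single-sequenced-affected."""
    if record.affected_sequenced == 0:
        raise ValueError(
            f"record for family {record.family_id} has no sequenced affected "
            "individuals and cannot be on the final list"
        )
    if record.affected_carriers != record.affected_sequenced:
        raise ValueError(
            f"record for family {record.family_id} violates the segregation "
            f"requirement ({record.affected_ratio})"
        )
    return (
        SharingClass.SHARED
        if record.affected_sequenced >= 2
        else SharingClass.SINGLE_AFFECTED
    )


def is_novel(variant: AnnotatedVariant) -> bool:
    """True if absent from dbSNP, ESP and 1000 Genomes alike."""
    return variant.dbsnp_id is None and variant.freqs.all_absent


def is_private(
    variant: AnnotatedVariant, records: Sequence[CandidateRecord]
) -> bool:
    """True if exactly one family carries a final-list record for ``variant``."""
    families = {r.family_id for r in records if r.variant.key == variant.key}
    return len(families) == 1


def genes_in_multiple_families(records: Iterable[CandidateRecord]) -> set[str]:
    """Gene symbols whose final-list records span >= 2 distinct families."""
    fam_by_gene: dict[str, set[str]] = {}
    for r in records:
        if r.variant.gene_symbol is not None:
            fam_by_gene.setdefault(r.variant.gene_symbol, set()).add(r.family_id)
    return {gene for gene, fams in fam_by_gene.items() if len(fams) >= 2}
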