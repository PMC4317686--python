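"""Packaged desk-scale fixtures.

Two small plain-text datasets ship with the package:

* ``affected_pedigree.ped`` — the affected members of the 20 sequenced
  glioma families (relationship rows flattened to individuals; parent
  links kept only where both ends are affected members).
* ``candidate_variants.tsv`` — the 21 final-list candidate variants with
  their per-family carrier ratios, population frequencies (percent),
  dbSNP ids and CADD scaled C-scores.

:func:`load_candidate_cohort` inflates the candidate table into a full
``Cohort`` whose genotype counts reproduce the printed carrier ratios,
together with a matching filter configuration (one exonic capture target
per candidate position) and all-concordant bidirectional Sanger
observations — the inputs needed to replay the post-Sanger triage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .filters import FilterConfig
from .io import default_cgc_genes, read_pedigree
from .model import (
    AnnotatedVariant,
    Cohort,
    Family,
    FunctionalClass,
    GenotypeCall,
    Individual,
    LinkageLocus,
    PopulationFrequencies,
    TargetInterval,
)
from .sanger import SangerObservation, StrandCall


def _data_path(name: str):
    return resources.as_file(resources.files("glioseg.data") / name)


def load_affected_pedigree() -> list[Family]:
    """The packaged 20-family affected-members pedigree."""
    with _data_path("affected_pedigree.ped") as p:
        return read_pedigree(p)


def _ratio(text: str) -> tuple[int, int]:
    num, den = text.split("/")
    return int(num), int(den)


@dataclass
class CandidateFixture:
    cohort: Cohort
    config: FilterConfig
    sanger_observations: list[SangerObservation]


def load_candidate_cohort(exonic_halfwidth: int = 50) -> CandidateFixture:
    """Inflate the packaged candidate table into a runnable cohort.

    For each family the member roster is reconstructed from the printed
    ratio denominators (consistent across that family's rows); carrier
    genotypes are assigned so every row's affected and unaffected ratios
    are reproduced exactly. Each candidate position gets an exonic capture
    target of ``2*exonic_halfwidth + 1`` bases centred on it.
    """
    with _data_path("candidate_variants.tsv") as p:
        df = pd.read_csv(p, sep="\t", dtype=str)

    # family rosters from the (consistent) denominators
    n_aff: dict[str, int] = {}
    n_unaff: dict[str, int] = {}
    for row in df.itertuples(index=False):
        _, aden = _ratio(row.affected_ratio)
        _, uden = _ratio(row.unaffected_ratio)
        for store, den in ((n_aff, aden), (n_unaff, uden)):
            if row.family_id in store and store[row.family_id] != den:
                raise ValueError(
                    f"inconsistent denominators for family {row.family_id}"
                )
            store[row.family_id] = den

    families = []
    for fid in sorted(n_aff):
        members = [
            Individual(f"{fid}-A{i}", fid, affected=True, sequenced=True)
            for i in range(1, n_aff[fid] + 1)
        ] + [
            Individual(f"{fid}-U{i}", fid, affected=False, sequenced=True)
            for i in range(1, n_unaff[fid] + 1)
        ]
        families.append(Family(fid, members))

    variants: list[AnnotatedVariant] = []
    genotypes: dict = {}
    targets: list[TargetInterval] = []
    observations: list[SangerObservation] = []

    def opt(value: str):
        return None if value in (".", "", None) or pd.isna(value) else value

    for row in df.itertuples(index=False):
        v = AnnotatedVariant(
            chrom="17",
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            gene_symbol=row.gene,
            functional_class=FunctionalClass.MISSENSE,
            dbsnp_id=opt(row.dbsnp),
            freqs=PopulationFrequencies(
                esp_percent=None if opt(row.esp_pct) is None else float(row.esp_pct),
                kg_percent=None if opt(row.kg_pct) is None else float(row.kg_pct),
            ),
            scaled_c_score=float(row.cadd_scaled),
        )
        variants.append(v)
        targets.append(
            TargetInterval(
                "17",
                v.pos - exonic_halfwidth,
                v.pos + exonic_halfwidth,
                exonic=True,
            )
        )
        anum, aden = _ratio(row.affected_ratio)
        unum, uden = _ratio(row.unaffected_ratio)
        fid = row.family_id
        for fam in families:
            for m in fam.members:
                if fam.family_id != fid:
                    genotypes[(v.key, m.individual_id)] = GenotypeCall.NON_CARRIER
        for i in range(1, aden + 1):
            genotypes[(v.key, f"{fid}-A{i}")] = (
                GenotypeCall.CARRIER_HET if i <= anum else GenotypeCall.NON_CARRIER
            )
        for i in range(1, uden + 1):
            genotypes[(v.key, f"{fid}-U{i}")] = (
                GenotypeCall.CARRIER_HET if i <= unum else GenotypeCall.NON_CARRIER
            )
        for i in range(1, anum + 1):
            observations.append(
                SangerObservation(
                    v.key, f"{fid}-A{i}", StrandCall.CONCORDANT, StrandCall.CONCORDANT
                )
            )

    cohort = Cohort(families=families, variants=variants, genotypes=genotypes)
    config = FilterConfig(
        linkage_locus=LinkageLocus(),
        target_intervals=sorted(targets, key=lambda t: (t.chrom, t.start)),
        cgc_genes=default_cgc_genes(),
    )
    return CandidateFixture(cohort, config, observations)
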