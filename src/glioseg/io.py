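"""Readers and writers for the external formats the pipeline touches.

Formats:

* PED pedigree file — six standard columns (family, individual, father,
  mother, sex, phenotype) plus three extension columns: ``sequenced``
  {0,1}, ``histology`` (string, ``.`` if unknown) and ``age_dx`` (years,
  ``.`` if unknown). Tab-separated so histology labels may contain spaces.
* VCF 4.x with per-sample GT fields (pysam; multi-allelic records are
  decomposed per ALT allele on read).
* Annotation TSV keyed by chrom/pos/ref/alt with header
  ``chrom pos ref alt gene func dbsnp esp_pct kg_pct kg_ceu_pct cadd_scaled``.
* BED (0-based half-open), converted to 1-based inclusive intervals on
  read; a 4th column equal to ``exonic`` flags coding-exon capture targets.
* Plain-text gene list (one symbol per line) and the Sanger read-call TSV
  ``variant_key individual_id fwd rev`` with calls in {C, D, N}.
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import pandas as pd
import pysam

from .model import (
    AnnotatedVariant,
    Cohort,
    Family,
    FunctionalClass,
    GenomicInterval,
    GenotypeCall,
    Individual,
    PopulationFrequencies,
    TargetInterval,
    VariantKey,
)
from .sanger import SangerObservation, StrandCall

logger = logging.getLogger(__name__)

GRCH37_CHR17_LENGTH = 83_257_441

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "func",
    "dbsnp", "esp_pct", "kg_pct", "kg_ceu_pct", "cadd_scaled",
]


class PedigreeParseError(ValueError):
    pass


def read_pedigree(path: str | os.PathLike) -> list[Family]:
    """Parse a PED-dialect file into families with resolved parent links.

    Phenotype column: 2 = affected; 1 = unaffected; 0 or -9 = unknown,
    treated as unaffected for all downstream filtering.
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated 6-column files
                fields = line.split()
            if len(fields) < 6:
                raise PedigreeParseError(
                    f"{path}: line {lineno}: expected >= 6 columns, got {len(fields)}"
                )
            fid, iid, father, mother, sex, pheno = fields[:6]
            sequenced = fields[6] if len(fields) > 6 else "0"
            histology = fields[7] if len(fields) > 7 else "."
            age = fields[8] if len(fields) > 8 else "."
            if pheno not in {"2", "1", "0", "-9"}:
                raise PedigreeParseError(
                    f"{path}: line {lineno}: bad phenotype code {pheno!r}"
                )
            try:
                ind = Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if father in ("0", ".") else father,
                    mother_id=None if mother in ("0", ".") else mother,
                    sex=_SEX_FROM_PED.get(sex, "unknown"),
                    affected=(pheno == "2"),
                    sequenced=(sequenced == "1"),
                    histology=None if histology in (".", "") else histology,
                    age_at_diagnosis=None if age in (".", "") else float(age),
                )
            except ValueError as exc:
                raise PedigreeParseError(f"{path}: line {lineno}: {exc}") from exc
            rows.setdefault(fid, []).append(ind)
    # Family construction validates parent links and raises naming the id
    return [Family(fid, members) for fid, members in rows.items()]


def write_pedigree(families: Sequence[Family], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for fam in families:
            for m in fam.members:
                fh.write(
                    "\t".join(
                        [
                            fam.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_TO_PED[m.sex],
                            "2" if m.affected else "1",
                            "1" if m.sequenced else "0",
                            m.histology or ".",
                            "." if m.age_at_diagnosis is None else f"{m.age_at_diagnosis:g}",
                        ]
                    )
                    + "\n"
                )


def _merge_sorted(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent 1-based closed intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged.pop()
            merged.append(GenomicInterval(last.chrom, last.start, max(last.end, iv.end)))
        else:
            merged.append(iv)
    return merged


def read_intervals(path: str | os.PathLike, merge: bool = True) -> list[GenomicInterval]:
    """Read a 3+-column BED file into 1-based inclusive intervals.

    BED records are 0-based half-open; record (chrom, s, e) becomes the
    closed interval [s+1, e]. Overlapping records are merged on load.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: BED end ({end}) <= start ({start})"
                )
            intervals.append(GenomicInterval(chrom, start + 1, end))
    return _merge_sorted(intervals) if merge else intervals


def read_targets(path: str | os.PathLike) -> list[TargetInterval]:
    """Read capture-target BED; name column ``exonic`` marks exon targets."""
    targets: list[TargetInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: BED end ({end}) <= start ({start})"
                )
            exonic = len(fields) > 3 and fields[3].lower() == "exonic"
            targets.append(TargetInterval(chrom, start + 1, end, exonic=exonic))
    return sorted(targets, key=lambda t: (t.chrom, t.start, t.end))


def write_targets(targets: Sequence[TargetInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in targets:
            name = "exonic" if t.exonic else "other"
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{name}\n")


def write_intervals(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def default_cgc_genes() -> set[str]:
    """The packaged 23-gene chromosome-17 Cancer Gene Census waiver set."""
    from importlib import resources

    with resources.as_file(
        resources.files("glioseg.data") / "cgc_chr17_genes.txt"
    ) as p:
        return load_cgc_genes(p)


def load_cgc_genes(path: str | os.PathLike) -> set[str]:
    """Load a plain-text gene list (one symbol per line) as a set."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    if not genes:
        logger.warning("gene list %s is empty", path)
    return genes


# ---------------------------------------------------------------------------
# annotation table


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip().rstrip("%")
        if value in (".", ""):
            return None
    return float(value)


def read_annotations(path: str | os.PathLike) -> dict[VariantKey, dict]:
    """Read the annotation TSV into a map keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation table lacks columns {sorted(missing)}")
    table: dict[VariantKey, dict] = {}
    for row in df.itertuples(index=False):
        key: VariantKey = (row.chrom, int(row.pos), row.ref, row.alt)
        if key in table:
            raise ValueError(f"{path}: duplicate annotation key {key}")
        table[key] = {
            "gene_symbol": row.gene if row.gene not in (".", "") else None,
            "functional_class": FunctionalClass(row.func)
            if row.func not in (".", "")
            else FunctionalClass.OTHER_NONCODING,
            "dbsnp_id": row.dbsnp if row.dbsnp not in (".", "") else None,
            "freqs": PopulationFrequencies(
                esp_percent=_opt_float(row.esp_pct),
                kg_percent=_opt_float(row.kg_pct),
                kg_ceu_percent=_opt_float(row.kg_ceu_pct),
            ),
            "scaled_c_score": _opt_float(row.cadd_scaled),
        }
    return table


def write_annotations(
    variants: Sequence[AnnotatedVariant], path: str | os.PathLike
) -> None:
    def fmt(v) -> str:
        return "." if v is None else f"{v:g}"

    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref_allele,
                        v.alt_allele,
                        v.gene_symbol or ".",
                        v.functional_class.value,
                        v.dbsnp_id or ".",
                        fmt(v.freqs.esp_percent),
                        fmt(v.freqs.kg_percent),
                        fmt(v.freqs.kg_ceu_percent),
                        fmt(v.scaled_c_score),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_variants(
    vcf_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    families: Sequence[Family],
) -> tuple[list[AnnotatedVariant], dict[tuple[VariantKey, str], GenotypeCall]]:
    """Read a genotyped VCF and join the annotation table.

    Multi-allelic records are decomposed into one :class:`AnnotatedVariant`
    per ALT allele. Every VCF sample must be a sequenced pedigree member.
    ``./.`` genotypes become :attr:`GenotypeCall.MISSING`.
    """
    sequenced = {
        m.individual_id for fam in families for m in fam.members if m.sequenced
    }
    annotations = read_annotations(annotation_path)

    variants: list[AnnotatedVariant] = []
    genotypes: dict[tuple[VariantKey, str], GenotypeCall] = {}
    with pysam.VariantFile(os.fspath(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = set(samples) - sequenced
        if unknown:
            raise ValueError(
                f"VCF samples not among sequenced pedigree members: {sorted(unknown)}"
            )
        for rec in vcf:
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                key: VariantKey = (rec.chrom, rec.pos, rec.ref, alt)
                ann = annotations.get(key, {})
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        **ann,
                    )
                )
                for sample in samples:
                    gt = rec.samples[sample].get("GT") or (None, None)
                    n_alt = sum(1 for a in gt if a == alt_index)
                    if n_alt >= 2:
                        call = GenotypeCall.CARRIER_HOM
                    elif n_alt == 1:
                        call = GenotypeCall.CARRIER_HET
                    elif any(a is None for a in gt):
                        call = GenotypeCall.MISSING
                    else:
                        call = GenotypeCall.NON_CARRIER
                    genotypes[(key, sample)] = call
    return variants, genotypes


def write_vcf(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write the cohort's genotypes as an uncompressed biallelic VCF."""
    header = pysam.VariantHeader()
    chrom_lengths: dict[str, int] = {}
    for v in cohort.variants:
        default = GRCH37_CHR17_LENGTH if v.chrom in ("17", "chr17") else 250_000_000
        chrom_lengths[v.chrom] = max(chrom_lengths.get(v.chrom, default), v.pos + 1000)
    for chrom, length in sorted(chrom_lengths.items()):
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = [m.individual_id for m in cohort.sequenced_individuals]
    for s in samples:
        header.add_sample(s)

    _GT = {
        GenotypeCall.CARRIER_HET: (0, 1),
        GenotypeCall.CARRIER_HOM: (1, 1),
        GenotypeCall.NON_CARRIER: (0, 0),
        GenotypeCall.MISSING: (None, None),
    }
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for v in sorted(cohort.variants, key=lambda v: (v.chrom, v.pos, v.alt_allele)):
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.id = v.dbsnp_id
            for s in samples:
                rec.samples[s]["GT"] = _GT[cohort.call(v, s)]
            out.write(rec)


def read_cohort(
    ped_path: str | os.PathLike,
    vcf_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
) -> Cohort:
    families = read_pedigree(ped_path)
    variants, genotypes = read_variants(vcf_path, annotation_path, families)
    return Cohort(families=families, variants=variants, genotypes=genotypes)


# ---------------------------------------------------------------------------
# Sanger read-call table


def read_sanger_observations(path: str | os.PathLike) -> list[SangerObservation]:
    """Read the Sanger TSV (variant_key individual_id fwd rev; C/D/N)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"variant_key", "individual_id", "fwd", "rev"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: Sanger table lacks columns {sorted(required - set(df.columns))}")
    obs = []
    for row in df.itertuples(index=False):
        chrom, pos, ref, alt = row.variant_key.split(":")
        obs.append(
            SangerObservation(
                variant_key=(chrom, int(pos), ref, alt),
                individual_id=row.individual_id,
                forward_call=StrandCall(row.fwd),
                reverse_call=StrandCall(row.rev),
            )
        )
    return obs


def write_sanger_observations(
    observations: Sequence[SangerObservation], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tindividual_id\tfwd\trev\n")
        for o in observations:
            chrom, pos, ref, alt = o.variant_key
            fh.write(
                f"{chrom}:{pos}:{ref}:{alt}\t{o.individual_id}"
                f"\t{o.forward_call.value}\t{o.reverse_call.value}\n"
            )
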