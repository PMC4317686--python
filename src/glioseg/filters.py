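"""The staged variant triage: initial filters, post-Sanger filters, audit.

The triage runs in two stages around a Sanger verification step.

Initial stage (applied to all annotated calls, selects variants for
Sanger verification):

1. *Linked Locus* — drop variants outside the linkage region, unless the
   gene is in the Cancer Gene Census (CGC) waiver set;
2. *Targeted Region* — drop variants more than ``target_pad_bases``
   (default 200) bases from every capture target; waived for CGC genes;
3. *Rare Variant* — drop variants with frequency > 5% in ESP or the
   1000 Genomes CEU population;
4. *Family Segregation* — drop variants not carried by every sequenced
   affected member of at least one family (this also removes variants
   seen only in unaffected relatives).

Post-Sanger stage (applied to the verified calls):

1. *Sanger Verification* — keep fully verified variants only;
2. *Linked Locus* — no CGC waiver this time;
3. *Very Rare Variant* — drop frequency > 0.1% in ESP or 1000 Genomes;
4. *Targeted Exome* — keep variants inside exonic capture targets (no pad);
5. *Protein Alteration* — keep protein-altering classes only
   (missense/nonsense/frameshift/splice).

All frequency thresholds are strict: a variant exactly at the threshold
is kept. Every stage records its input/output counts and the dropped
variants in an :class:`AuditTrail`; each variant is attributed to the
first stage that drops it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Optional, Sequence

from .io import default_cgc_genes
from .model import (
    AnnotatedVariant,
    Cohort,
    FunctionalClass,
    GenomicInterval,
    LinkageLocus,
    PopulationFrequencies,
    PROTEIN_ALTERING,
    TargetInterval,
    VariantKey,
)
from .sanger import VerificationStatus
from .segregation import carrier_ratios
from .model import CandidateRecord

#: Frequency fields tested by the initial (5%) common-variant filter.
INITIAL_MAF_FIELDS: tuple[str, ...] = ("esp", "kg_ceu")
#: Frequency fields tested by the final (0.1%) very-rare-variant filter.
FINAL_MAF_FIELDS: tuple[str, ...] = ("esp", "kg", "kg_ceu")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class FilterConfig:
    """Thresholds and reference sets for both triage stages."""

    linkage_locus: LinkageLocus = field(default_factory=LinkageLocus)
    target_intervals: list[TargetInterval] = field(default_factory=list)
    target_pad_bases: int = 200
    cgc_genes: set[str] = field(default_factory=default_cgc_genes)
    initial_maf_threshold_percent: float = 5.0
    final_maf_threshold_percent: float = 0.1
    protein_altering_classes: frozenset[FunctionalClass] = PROTEIN_ALTERING

    def __post_init__(self) -> None:
        for name in ("initial_maf_threshold_percent", "final_maf_threshold_percent"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name}={v} outside (0, 100)")
        if self.target_pad_bases < 0:
            raise ValueError("target_pad_bases must be >= 0")


@dataclass(frozen=True)
class StageRecord:
    stage_name: str
    variants_in: int
    variants_out: int
    dropped_variant_keys: tuple[VariantKey, ...]

    def __post_init__(self) -> None:
        if self.variants_out != self.variants_in - len(self.dropped_variant_keys):
            raise ValueError(
                f"stage {self.stage_name}: out ({self.variants_out}) != "
                f"in ({self.variants_in}) - dropped ({len(self.dropped_variant_keys)})"
            )


@dataclass
class AuditTrail:
    """Per-stage counts plus a per-variant fate (first dropping stage)."""

    stages: list[StageRecord] = field(default_factory=list)
    fate: dict[VariantKey, str] = field(default_factory=dict)

    PASSED = "passed"

    def record_stage(
        self,
        stage_name: str,
        variants_in: Sequence[AnnotatedVariant],
        survivors: Sequence[AnnotatedVariant],
    ) -> None:
        if self.stages and self.stages[-1].variants_out != len(variants_in):
            raise ValueError(
                f"stage chain broken: {self.stages[-1].stage_name} emitted "
                f"{self.stages[-1].variants_out} but {stage_name} received "
                f"{len(variants_in)}"
            )
        surviving = {v.key for v in survivors}
        dropped = tuple(v.key for v in variants_in if v.key not in surviving)
        self.stages.append(
            StageRecord(stage_name, len(variants_in), len(survivors), dropped)
        )
        for key in dropped:
            self.fate.setdefault(key, stage_name)

    def finalize(self, survivors: Sequence[AnnotatedVariant]) -> None:
        for v in survivors:
            self.fate.setdefault(v.key, self.PASSED)


# ---------------------------------------------------------------------------
# predicates (True = keep)


def in_linkage_locus(
    pos: int, locus: LinkageLocus, chrom: Optional[str] = None
) -> bool:
    """True iff ``pos`` lies inside any linkage interval (closed endpoints)."""
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    for iv in locus.intervals:
        if chrom is not None and _norm_chrom(iv.chrom) != _norm_chrom(chrom):
            continue
        if pos in iv:
            return True
    return False


def linked_locus_filter(
    variant: AnnotatedVariant, cfg: FilterConfig, waive_cgc: bool = False
) -> bool:
    """Keep variants inside the linkage region (CGC genes optionally waived)."""
    if in_linkage_locus(variant.pos, cfg.linkage_locus, chrom=variant.chrom):
        return True
    return waive_cgc and variant.gene_symbol in cfg.cgc_genes


def targeted_region_filter(
    variant: AnnotatedVariant,
    cfg: FilterConfig,
    mode: str = "padded",
    waive_cgc: bool = False,
) -> bool:
    """Proximity gate against the capture design.

    ``padded`` mode keeps variants within ``target_pad_bases`` of any
    target (distance 0 inside; a tie at exactly the pad is kept);
    ``exonic`` mode keeps variants strictly inside an exonic-flagged
    target, with no pad.
    """
    if not cfg.target_intervals:
        raise ValueError("FilterConfig.target_intervals is empty")
    if mode not in ("padded", "exonic"):
        raise ValueError(f"unknown mode {mode!r}")
    if waive_cgc and variant.gene_symbol in cfg.cgc_genes:
        return True
    chrom = _norm_chrom(variant.chrom)
    for t in cfg.target_intervals:
        if _norm_chrom(t.chrom) != chrom:
            continue
        if mode == "padded":
            if t.distance_to(variant.pos) <= cfg.target_pad_bases:
                return True
        else:
            if t.exonic and variant.pos in t:
                return True
    return False


def maf_filter(
    freqs: PopulationFrequencies,
    threshold_percent: float,
    fields: Sequence[str],
) -> bool:
    """Keep unless ANY tested, present frequency strictly exceeds the threshold.

    Missing frequencies never trigger a drop: a variant absent from every
    database is by definition rarer than any threshold.
    """
    if not (0.0 < threshold_percent < 100.0):
        raise ValueError(f"threshold_percent={threshold_percent} outside (0, 100)")
    for which in fields:
        value = freqs.get(which)
        if value is not None and value > threshold_percent:
            return False
    return True


def family_segregation_filter(
    variant: AnnotatedVariant, cohort: Cohort
) -> tuple[bool, list[str]]:
    """Keep iff >= 1 family's sequenced affected members ALL carry the variant.

    A family with no sequenced affected members is never segregating; a
    variant carried only by unaffected relatives is therefore dropped.
    Returns the keep decision and the segregating family ids.
    """
    segregating = []
    for fam in cohort.families:
        affected = fam.sequenced_affected
        if affected and all(
            cohort.is_carrier(variant, m.individual_id) for m in affected
        ):
            segregating.append(fam.family_id)
    return bool(segregating), segregating


def protein_alteration_filter(variant: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Keep variants whose functional class changes the protein product."""
    return variant.functional_class in cfg.protein_altering_classes


# ---------------------------------------------------------------------------
# staged runners


def _apply(
    trail: AuditTrail,
    stage_name: str,
    variants: list[AnnotatedVariant],
    keep: Callable[[AnnotatedVariant], bool],
) -> list[AnnotatedVariant]:
    survivors = [v for v in variants if keep(v)]
    trail.record_stage(stage_name, variants, survivors)
    return survivors


def run_initial_stage(
    cohort: Cohort, cfg: FilterConfig
) -> tuple[list[AnnotatedVariant], AuditTrail]:
    """Run the pre-Sanger filter chain over the cohort's annotated variants."""
    trail = AuditTrail()
    variants = list(cohort.variants)
    variants = _apply(
        trail, "Linked Locus", variants,
        lambda v: linked_locus_filter(v, cfg, waive_cgc=True),
    )
    variants = _apply(
        trail, "Targeted Region", variants,
        lambda v: targeted_region_filter(v, cfg, mode="padded", waive_cgc=True),
    )
    variants = _apply(
        trail, "Rare Variant", variants,
        lambda v: maf_filter(
            v.freqs, cfg.initial_maf_threshold_percent, INITIAL_MAF_FIELDS
        ),
    )
    variants = _apply(
        trail, "Family Segregation", variants,
        lambda v: family_segregation_filter(v, cohort)[0],
    )
    trail.finalize(variants)
    return variants, trail


def run_post_sanger_stage(
    variants: Sequence[AnnotatedVariant],
    statuses: Mapping[VariantKey, VerificationStatus],
    cohort: Cohort,
    cfg: FilterConfig,
) -> tuple[list[CandidateRecord], AuditTrail]:
    """Run the post-Sanger filter chain and emit per-family candidate records.

    ``statuses`` must cover every input variant. The CGC waiver does not
    apply here: the final list is required to lie inside the linkage
    region.
    """
    missing = [v.key_str for v in variants if v.key not in statuses]
    if missing:
        raise ValueError(f"variants lacking Sanger verification status: {missing}")

    trail = AuditTrail()
    remaining = list(variants)
    remaining = _apply(
        trail, "Sanger Verification", remaining,
        lambda v: statuses[v.key] is VerificationStatus.FULLY_VERIFIED,
    )
    remaining = _apply(
        trail, "Linked Locus", remaining,
        lambda v: linked_locus_filter(v, cfg, waive_cgc=False),
    )
    remaining = _apply(
        trail, "Very Rare Variant", remaining,
        lambda v: maf_filter(
            v.freqs, cfg.final_maf_threshold_percent, FINAL_MAF_FIELDS
        ),
    )
    remaining = _apply(
        trail, "Targeted Exome", remaining,
        lambda v: targeted_region_filter(v, cfg, mode="exonic"),
    )
    remaining = _apply(
        trail, "Protein Alteration", remaining,
        lambda v: protein_alteration_filter(v, cfg),
    )
    seg: dict[VariantKey, list[str]] = {}
    for v in remaining:
        keep, fams = family_segregation_filter(v, cohort)
        if keep:
            seg[v.key] = fams
    remaining = _apply(
        trail, "Family Segregation", remaining, lambda v: v.key in seg
    )
    trail.finalize(remaining)

    records = [
        carrier_ratios(v, cohort.family(fid), cohort)
        for v in remaining
        for fid in seg[v.key]
    ]
    return records, trail


def verify_batch(
    variants: Sequence[AnnotatedVariant],
    observations: Sequence["SangerObservation"],
    cohort: Cohort,
) -> dict[VariantKey, "VerificationStatus"]:
    """Classify each variant's Sanger evidence against its NGS carriers.

    The expected-carrier set for a variant is its sequenced affected NGS
    carriers across the whole cohort; full verification requires both
    strands concordant in every one of them.
    """
    from .sanger import verify_variant

    by_key: dict[VariantKey, list] = {}
    for o in observations:
        by_key.setdefault(tuple(o.variant_key), []).append(o)
    statuses = {}
    for v in variants:
        expected = [
            m.individual_id
            for fam in cohort.families
            for m in fam.sequenced_affected
            if cohort.is_carrier(v, m.individual_id)
        ]
        statuses[v.key] = verify_variant(by_key.get(v.key, []), expected)
    return statuses


@dataclass
class PipelineResult:
    """Everything the two-stage triage produces for one cohort."""

    records: list[CandidateRecord]
    initial_trail: AuditTrail
    post_trail: AuditTrail
    statuses: dict

    @property
    def combined_fate(self) -> dict[VariantKey, str]:
        """First dropping stage across both stages, or "passed"."""
        return {**self.initial_trail.fate, **self.post_trail.fate}

    @property
    def surviving_variants(self) -> list[AnnotatedVariant]:
        seen = {}
        for r in self.records:
            seen.setdefault(r.variant.key, r.variant)
        return list(seen.values())


def run_full_pipeline(
    cohort: Cohort,
    observations: Sequence["SangerObservation"],
    cfg: FilterConfig,
) -> PipelineResult:
    """Initial filters, Sanger verification, post-Sanger filters, records."""
    initial_survivors, initial_trail = run_initial_stage(cohort, cfg)
    statuses = verify_batch(initial_survivors, observations, cohort)
    records, post_trail = run_post_sanger_stage(
        initial_survivors, statuses, cohort, cfg
    )
    return PipelineResult(records, initial_trail, post_trail, statuses)


def audit_percentages(trail: AuditTrail) -> list[tuple[str, Optional[float]]]:
    """Per-stage percent retained (100*out/in), rounded half-up to 1 decimal.

    A stage with zero input reports ``None`` rather than raising.
    """
    if not trail.stages:
        raise ValueError("audit trail has no stages")
    out = []
    for s in trail.stages:
        if s.variants_in == 0:
            out.append((s.stage_name, None))
        else:
            pct = (
                Decimal(100) * Decimal(s.variants_out) / Decimal(s.variants_in)
            ).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
            out.append((s.stage_name, float(pct)))
    return out


def retained_percent(n_in: int, n_out: int) -> Optional[float]:
    """100*n_out/n_in rounded half-up to one decimal; None if n_in = 0."""
    if n_in == 0:
        return None
    return float(
        (Decimal(100) * Decimal(n_out) / Decimal(n_in)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
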