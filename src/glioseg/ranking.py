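"""CADD-tier classification, deterministic ranking and report rendering.

The CADD scaled C-score is a phred-like deleteriousness rank: >= 10 puts
a substitution in the predicted top 10% most deleterious possible
substitutions in the human genome, >= 20 in the top 1%, >= 30 in the top
0.1%. Candidates are ranked by descending C-score with ascending genomic
position as the tie-break; variants without a score rank last (score
availability is an annotation property, not a filter).
"""

from __future__ import annotations

import enum
import json
import os
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

from .filters import AuditTrail, retained_percent
from .model import CandidateRecord
from .segregation import (
    SharingClass,
    classify_sharing,
    genes_in_multiple_families,
    is_novel,
    is_private,
)

CANDIDATE_COLUMNS = [
    "FamilyID", "Chr17Position", "RefAllele", "VarAllele", "GeneSymbol",
    "ESPFreqPct", "KGFreqPct", "dbSNP", "AffectedRatio", "UnaffectedRatio",
    "ScaledCScore", "SharingClass", "Novel", "Private",
]


class DeleteriousnessTier(enum.IntEnum):
    """Predicted-deleteriousness tier; higher value = more severe."""

    BELOW_TOP_10PCT = 0  # C < 10
    TOP_10PCT = 1  # 10 <= C < 20
    TOP_1PCT = 2  # 20 <= C < 30
    TOP_0_1PCT = 3  # C >= 30

    @property
    def label(self) -> str:
        return {
            DeleteriousnessTier.TOP_0_1PCT: "top_0.1pct",
            DeleteriousnessTier.TOP_1PCT: "top_1pct",
            DeleteriousnessTier.TOP_10PCT: "top_10pct",
            DeleteriousnessTier.BELOW_TOP_10PCT: "below_top_10pct",
        }[self]


def deleteriousness_tier(c: Optional[float]) -> Optional[DeleteriousnessTier]:
    """Tier of a scaled C-score; closed lower bounds; None if no score."""
    if c is None:
        return None
    if c < 0:
        raise ValueError(f"scaled C-score must be >= 0, got {c}")
    if c >= 30:
        return DeleteriousnessTier.TOP_0_1PCT
    if c >= 20:
        return DeleteriousnessTier.TOP_1PCT
    if c >= 10:
        return DeleteriousnessTier.TOP_10PCT
    return DeleteriousnessTier.BELOW_TOP_10PCT


def rank_candidates(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Stable sort: descending C-score, position tie-break, missing scores last."""

    def sort_key(r: CandidateRecord):
        c = r.variant.scaled_c_score
        return (c is None, -c if c is not None else 0.0, r.variant.chrom, r.variant.pos)

    return sorted(records, key=sort_key)


def _fmt(value) -> str:
    return "." if value is None else (f"{value:g}" if isinstance(value, float) else str(value))


def summarize(
    records: Sequence[CandidateRecord], trail: Optional[AuditTrail] = None
) -> dict:
    """Build the summary dictionary reported alongside the candidate table."""
    ranked = rank_candidates(records)
    sharing = [classify_sharing(r) for r in ranked]
    n_shared = sum(1 for s in sharing if s is SharingClass.SHARED)
    novel_shared = sum(
        1
        for r, s in zip(ranked, sharing)
        if s is SharingClass.SHARED and is_novel(r.variant)
    )
    tier_counts: Counter = Counter()
    for r in ranked:
        tier = deleteriousness_tier(r.variant.scaled_c_score)
        tier_counts[tier.label if tier is not None else "unscored"] += 1
    summary = {
        "n_candidates": len(ranked),
        "n_shared": n_shared,
        "n_single_affected": len(ranked) - n_shared,
        "n_novel_shared": novel_shared,
        "multi_family_genes": sorted(genes_in_multiple_families(ranked)),
        "tier_counts": dict(sorted(tier_counts.items())),
        "stage_counts": [
            {
                "stage": s.stage_name,
                "in": s.variants_in,
                "out": s.variants_out,
                "pct_retained": retained_percent(s.variants_in, s.variants_out),
            }
            for s in (trail.stages if trail is not None else [])
        ],
    }
    return summary


def render_reports(
    records: Sequence[CandidateRecord],
    trail: Optional[AuditTrail],
    out_dir: str | os.PathLike,
) -> list[Path]:
    """Write candidates.tsv, audit_trail.tsv/.json and summary.json.

    Returns the written paths. The candidate table mirrors the final-list
    layout: one row per (variant, family), ranked by C-score.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ranked = rank_candidates(records)

    candidates_path = out / "candidates.tsv"
    with open(candidates_path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for r in ranked:
            v = r.variant
            fh.write(
                "\t".join(
                    [
                        r.family_id,
                        str(v.pos),
                        v.ref_allele,
                        v.alt_allele,
                        _fmt(v.gene_symbol),
                        _fmt(v.freqs.esp_percent),
                        _fmt(v.freqs.kg_percent),
                        _fmt(v.dbsnp_id),
                        r.affected_ratio,
                        r.unaffected_ratio,
                        _fmt(v.scaled_c_score),
                        classify_sharing(r).value,
                        str(is_novel(v)),
                        str(is_private(v, ranked)),
                    ]
                )
                + "\n"
            )

    written = [candidates_path]
    if trail is not None:
        trail_tsv = out / "audit_trail.tsv"
        with open(trail_tsv, "w") as fh:
            fh.write("stage\tvariants_in\tvariants_out\tpct_retained\n")
            for s in trail.stages:
                fh.write(
                    f"{s.stage_name}\t{s.variants_in}\t{s.variants_out}"
                    f"\t{_fmt(retained_percent(s.variants_in, s.variants_out))}\n"
                )
        trail_json = out / "audit_trail.json"
        with open(trail_json, "w") as fh:
            json.dump(
                {
                    "stages": [
                        {
                            "stage": s.stage_name,
                            "in": s.variants_in,
                            "out": s.variants_out,
                            "dropped": [":".join(map(str, k)) for k in s.dropped_variant_keys],
                        }
                        for s in trail.stages
                    ],
                    "fate": {
                        ":".join(map(str, k)): stage for k, stage in trail.fate.items()
                    },
                },
                fh,
                indent=2,
            )
        written += [trail_tsv, trail_json]

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summarize(ranked, trail), fh, indent=2)
    written.append(summary_path)
    return written


def read_candidates(path: str | os.PathLike) -> list[dict]:
    """Re-read candidates.tsv rows as dictionaries (round-trip check)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df.to_dict(orient="records")
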