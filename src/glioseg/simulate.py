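"""Seeded synthetic family-cohort generator with a planted truth table.

The generator emulates the statistical structure the triage assumes:

* multi-generation pedigrees with 2 (83%) or 3+ (17%) affected blood
  relatives per family, a mix of sequenced and unsequenced members, and a
  configurable fraction of families with at least one sequenced affected
  member;
* a capture design of short exonic and non-exonic targets tiled through
  the two linkage intervals (plus a few exonic targets outside the
  locus, so the locus gate can be violated in isolation);
* planted candidate variants — very rare or database-absent missense
  alleles dropped through one family's pedigree Mendelian-consistently
  from a founder, so that every sequenced affected member carries them;
* decoy variants, each engineered to violate exactly one triage
  predicate while satisfying all others;
* background variants with allele frequencies from a mixture of a point
  mass at "absent from databases" and a log-uniform spectrum.

Sanger read calls are emitted for every variant with an affected carrier
(excluded variants are verified too): concordant bidirectional reads
except for the ``sanger_partial`` / ``sanger_failed`` decoy classes.

Every variant carries an intended fate (the first filter stage expected
to drop it, or "passed") in a :class:`TruthTable`; the fate of planted
variants and decoys is fixed by construction, while background variants
are scored by a small self-contained predicate evaluator that is kept
independent of :mod:`glioseg.filters`.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .filters import FilterConfig
from .io import (
    default_cgc_genes,
    write_annotations,
    write_intervals,
    write_pedigree,
    write_sanger_observations,
    write_targets,
    write_vcf,
)
from .model import (
    AnnotatedVariant,
    Cohort,
    Family,
    FunctionalClass,
    GenomicInterval,
    GenotypeCall,
    Individual,
    LinkageLocus,
    PopulationFrequencies,
    TargetInterval,
    VariantKey,
)
from .sanger import SangerObservation, StrandCall

DECOY_CLASSES = (
    "common_freq",
    "off_locus",
    "off_target",
    "non_segregating",
    "unaffected_only",
    "synonymous",
    "sanger_partial",
    "sanger_failed",
)

PASSED = "passed"


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; ``seed`` fixes all randomness."""

    n_families: int = 12
    pedigree_depth: int = 3  # generations, 2-4
    n_affected_per_family: Optional[int] = None  # None: draw from mixture
    #: (count, weight) mixture for affected members per family; the default
    #: reflects a cohort where 83% of families have exactly two affected.
    affected_mixture: tuple[tuple[int, float], ...] = ((2, 0.83), (3, 0.17))
    p_sequenced: float = 0.85
    #: fraction of families forced to have >= 1 sequenced affected member
    #: (probands of the rest failed sequencing), mirroring 20 of 23.
    p_family_sequenced_affected: float = 20 / 23
    n_planted_candidates: int = 4
    decoys_per_class: int = 1
    background_variant_count: int = 40
    #: probability a background variant is absent from every database
    freq_absent_mass: float = 0.4
    #: log-uniform background MAF range, percent
    freq_range_percent: tuple[float, float] = (0.01, 20.0)
    seed: int = 0
    linkage_locus: LinkageLocus = field(default_factory=LinkageLocus)
    n_exonic_targets: int = 90
    n_other_targets: int = 30
    n_offlocus_exonic_targets: int = 6
    target_length: int = 120
    target_pad_bases: int = 200

    def __post_init__(self) -> None:
        for name in ("p_sequenced", "p_family_sequenced_affected", "freq_absent_mass"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if not (2 <= self.pedigree_depth <= 4):
            raise SimConfigError("pedigree_depth must be in 2..4")
        for name in (
            "n_families", "n_planted_candidates", "decoys_per_class",
            "background_variant_count",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.n_affected_per_family is not None and self.n_affected_per_family < 1:
            raise SimConfigError("n_affected_per_family must be >= 1")


@dataclass
class TruthRecord:
    variant_key: str  # "chrom:pos:ref:alt"
    category: str  # "planted" | "decoy:<class>" | "background"
    intended_fate: str  # "passed" or first dropping stage name
    planted_family_ids: list[str]
    #: full carrier pattern over ALL pedigree members (sequenced or not)
    carrier_pattern: dict[str, str]  # individual_id -> "carrier-het" | ...


@dataclass
class TruthTable:
    records: dict[str, TruthRecord] = field(default_factory=dict)

    def add(self, rec: TruthRecord) -> None:
        if rec.variant_key in self.records:
            raise ValueError(f"duplicate truth entry {rec.variant_key}")
        self.records[rec.variant_key] = rec

    @property
    def passes(self) -> set[str]:
        return {k for k, r in self.records.items() if r.intended_fate == PASSED}

    def to_json(self) -> str:
        return json.dumps(
            {k: asdict(r) for k, r in sorted(self.records.items())}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        table = cls()
        for key, raw in json.loads(text).items():
            table.add(TruthRecord(**raw))
        return table


@dataclass
class SimResult:
    cohort: Cohort
    observations: list[SangerObservation]
    filter_config: FilterConfig
    truth: TruthTable
    sim_config: SimConfig


# ---------------------------------------------------------------------------
# pedigrees


def generate_pedigrees(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> list[Family]:
    """Generate connected multi-generation pedigrees with affected relatives.

    Blood members all descend from one founder couple; spouses marry in
    as unrelated founders. Affected statuses go to blood members only;
    sequenced flags are Bernoulli(``p_sequenced``), with one affected
    member forced sequenced in a ``p_family_sequenced_affected`` fraction
    of families (and all affected forced unsequenced in the rest).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    families = []
    for fi in range(cfg.n_families):
        fid = f"F{fi:02d}"
        people: dict[str, dict] = {}

        def add(iid, father, mother, sex, blood):
            people[iid] = dict(
                individual_id=iid, father_id=father, mother_id=mother,
                sex=sex, blood=blood,
            )

        n = [0]

        def new_id() -> str:
            n[0] += 1
            return f"{fid}-I{n[0]:02d}"

        pa, ma = new_id(), new_id()
        add(pa, None, None, "male", True)
        add(ma, None, None, "female", True)
        couples = [(pa, ma)]
        for gen in range(1, cfg.pedigree_depth):
            nxt = []
            for father, mother in couples:
                for _ in range(int(rng.integers(2, 4))):
                    cid = new_id()
                    sex = "male" if rng.random() < 0.5 else "female"
                    add(cid, father, mother, sex, True)
                    if gen < cfg.pedigree_depth - 1 and rng.random() < 0.7:
                        sid = new_id()
                        add(sid, None, None,
                            "female" if sex == "male" else "male", False)
                        nxt.append((cid, sid) if sex == "male" else (sid, cid))
            couples = nxt

        blood_ids = [iid for iid, p in people.items() if p["blood"]]
        if cfg.n_affected_per_family is not None:
            n_affected = cfg.n_affected_per_family
        else:
            counts = [c for c, _ in cfg.affected_mixture]
            weights = np.array([w for _, w in cfg.affected_mixture], dtype=float)
            n_affected = int(rng.choice(counts, p=weights / weights.sum()))
        if n_affected > len(blood_ids):
            raise SimConfigError(
                f"family {fid}: {n_affected} affected requested but only "
                f"{len(blood_ids)} blood members generated"
            )
        affected = {str(x) for x in rng.choice(blood_ids, size=n_affected, replace=False)}
        sequenced = {iid for iid in people if rng.random() < cfg.p_sequenced}
        if rng.random() < cfg.p_family_sequenced_affected:
            forced = sorted(affected)[int(rng.integers(0, len(affected)))]
            sequenced.add(forced)
        else:
            sequenced -= affected  # probands' specimens failed sequencing

        members = [
            Individual(
                individual_id=iid,
                family_id=fid,
                father_id=p["father_id"],
                mother_id=p["mother_id"],
                sex=p["sex"],
                affected=iid in affected,
                sequenced=iid in sequenced,
                age_at_diagnosis=float(rng.integers(10, 80)) if iid in affected else None,
                histology="glioma" if iid in affected else None,
            )
            for iid, p in people.items()
        ]
        families.append(Family(fid, members))
    return families


# ---------------------------------------------------------------------------
# gene drop


def _lineage_to_founder(family: Family, individual_id: str) -> tuple[list[str], str]:
    """Path of blood ancestors from ``individual_id`` up to a top founder.

    Returns (path including the individual and the reached founder, founder id).
    """
    members = {m.individual_id: m for m in family.members}
    path = [individual_id]
    cur = members[individual_id]
    while cur.father_id is not None or cur.mother_id is not None:
        # exactly one parent chain leads toward the founder couple; prefer
        # the parent that itself has parents (a blood member), else either
        father = members.get(cur.father_id) if cur.father_id else None
        mother = members.get(cur.mother_id) if cur.mother_id else None
        nxt = None
        for cand in (father, mother):
            if cand is not None and (cand.father_id or cand.mother_id):
                nxt = cand
                break
        if nxt is None:
            # both parents are founders; the male top founder introduces
            nxt = father if father is not None else mother
        path.append(nxt.individual_id)
        cur = nxt
    return path, cur.individual_id


def gene_drop(
    family: Family,
    rng: np.random.Generator,
    founder_carriers: set[str],
    forced_carriers: set[str] = frozenset(),
) -> dict[str, GenotypeCall]:
    """Drop one rare allele through the pedigree under Mendelian transmission.

    Founders in ``founder_carriers`` start heterozygous; every other
    member inherits the allele from a carrier parent with probability
    1/2. Members in ``forced_carriers`` (which must form parent-linked
    chains from a carrier founder) are set to carriers deterministically.
    Returns the full carrier pattern over all members.
    """
    members = {m.individual_id: m for m in family.members}
    calls: dict[str, GenotypeCall] = {}

    def resolve(iid: str) -> GenotypeCall:
        if iid in calls:
            return calls[iid]
        m = members[iid]
        if m.father_id is None and m.mother_id is None:
            carrier = iid in founder_carriers or iid in forced_carriers
        elif iid in forced_carriers:
            carrier = True
        else:
            carrier = False
            for pid in (m.father_id, m.mother_id):
                if pid is not None and resolve(pid).is_carrier and rng.random() < 0.5:
                    carrier = True
        calls[iid] = GenotypeCall.CARRIER_HET if carrier else GenotypeCall.NON_CARRIER
        return calls[iid]

    # resolve parents before children deterministically by insertion order
    for m in family.members:
        resolve(m.individual_id)
    return calls


def _forced_drop_to(
    family: Family, rng: np.random.Generator, targets: list[str]
) -> dict[str, GenotypeCall]:
    """Gene drop guaranteed to make every ``target`` a carrier."""
    forced: set[str] = set()
    founders: set[str] = set()
    for t in targets:
        path, founder = _lineage_to_founder(family, t)
        forced.update(path)
        founders.add(founder)
    return gene_drop(family, rng, founders, forced)


def _partial_segregation_drop(
    family: Family, rng: np.random.Generator, max_tries: int = 200
) -> dict[str, GenotypeCall]:
    """Drop making >= 1 but not all sequenced affected members carriers.

    The forced target is a sequenced affected member whose founder lineage
    contains no other sequenced affected member (always exists: an
    individual of minimal generation qualifies); chance co-carriage of the
    remaining affected members is removed by rejection sampling so the
    pattern stays Mendelian-consistent.
    """
    aff_ids = [m.individual_id for m in family.sequenced_affected]
    if len(aff_ids) < 2:
        raise SimConfigError("partial segregation needs >= 2 sequenced affected")
    target = None
    for cand in aff_ids:
        path, _ = _lineage_to_founder(family, cand)
        if not (set(path[1:]) & set(aff_ids)):
            target = cand
            break
    if target is None:  # pragma: no cover - minimal-generation member qualifies
        raise SimConfigError("no valid partial-segregation target")
    others = [a for a in aff_ids if a != target]
    for _ in range(max_tries):
        calls = _forced_drop_to(family, rng, [target])
        if not all(calls[o].is_carrier for o in others):
            return calls
    raise SimConfigError("could not sample a non-segregating pattern")


# ---------------------------------------------------------------------------
# capture design


def make_targets(cfg: SimConfig) -> list[TargetInterval]:
    """Tile exonic and non-exonic capture targets; a few exonic off-locus."""
    targets: list[TargetInterval] = []
    ivs = cfg.linkage_locus.intervals
    total = sum(iv.length for iv in ivs)
    L = cfg.target_length

    def tile(iv: GenomicInterval, k: int, exonic: bool, phase: int) -> None:
        if k <= 0:
            return
        step = max(L * 3, (iv.length - 2 * L) // k)
        pos = iv.start + L + phase
        for _ in range(k):
            if pos + L > iv.end:
                break
            targets.append(TargetInterval(iv.chrom, pos, pos + L - 1, exonic=exonic))
            pos += step

    for iv in ivs:
        share = iv.length / total
        tile(iv, max(1, round(cfg.n_exonic_targets * share)), True, 0)
        tile(iv, max(1, round(cfg.n_other_targets * share)), False, 2 * L)
    # exonic targets outside the locus (same chromosome, well below it)
    off = GenomicInterval(ivs[0].chrom, 20_000_000, 30_000_000)
    tile(off, cfg.n_offlocus_exonic_targets, True, 0)
    return sorted(targets, key=lambda t: (t.chrom, t.start))


# ---------------------------------------------------------------------------
# independent fate evaluator (deliberately not using glioseg.filters)


def _evaluate_fate(
    v: AnnotatedVariant,
    carrier_sets: dict[str, set[str]],  # family_id -> carrier individual ids
    families: list[Family],
    targets: list[TargetInterval],
    locus: LinkageLocus,
    cgc: set[str],
    pad: int,
    sanger_class: str,  # "full" | "partial" | "failed" | "none"
) -> str:
    in_locus = any(
        iv.chrom == v.chrom and iv.start <= v.pos <= iv.end for iv in locus.intervals
    )
    waived = v.gene_symbol in cgc
    near_target = False
    in_exonic = False
    for t in targets:
        if t.chrom != v.chrom:
            continue
        d = t.start - v.pos if v.pos < t.start else (v.pos - t.end if v.pos > t.end else 0)
        if d <= pad:
            near_target = True
        if t.exonic and d == 0:
            in_exonic = True
    segregating = False
    for fam in families:
        aff = [m.individual_id for m in fam.members if m.affected and m.sequenced]
        if aff and all(a in carrier_sets.get(fam.family_id, set()) for a in aff):
            segregating = True
            break
    fq = [v.freqs.esp_percent, v.freqs.kg_percent, v.freqs.kg_ceu_percent]

    if not in_locus and not waived:
        return "Linked Locus"
    if not near_target and not waived:
        return "Targeted Region"
    if any(f is not None and f > 5.0 for f in (v.freqs.esp_percent, v.freqs.kg_ceu_percent)):
        return "Rare Variant"
    if not segregating:
        return "Family Segregation"
    if sanger_class != "full":
        return "Sanger Verification"
    if not in_locus:
        return "Linked Locus"
    if any(f is not None and f > 0.1 for f in fq):
        return "Very Rare Variant"
    if not in_exonic:
        return "Targeted Exome"
    if v.functional_class not in (
        FunctionalClass.MISSENSE,
        FunctionalClass.NONSENSE,
        FunctionalClass.FRAMESHIFT,
        FunctionalClass.SPLICE,
    ):
        return "Protein Alteration"
    return PASSED


# ---------------------------------------------------------------------------
# variant planting


_BASES = ("A", "C", "G", "T")


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(0, 4))]
    alt = _BASES[int(rng.integers(0, 4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(0, 4))]
    return ref, alt


class _PositionPool:
    """Draw unique variant positions relative to the capture design."""

    def __init__(self, cfg: SimConfig, targets: list[TargetInterval], rng):
        self.cfg = cfg
        self.rng = rng
        self.used: set[int] = set()
        locus = cfg.linkage_locus
        self.exonic_in = [
            t for t in targets
            if t.exonic and any(t.start in iv and t.end in iv for iv in locus.intervals)
        ]
        self.exonic_out = [
            t for t in targets
            if t.exonic and not any(t.start in iv for iv in locus.intervals)
        ]
        self.nonexonic_in = [
            t for t in targets
            if not t.exonic and any(t.start in iv for iv in locus.intervals)
        ]
        self.all_targets = targets

    def _unique(self, pos: int) -> int:
        while pos in self.used:
            pos += 1
        self.used.add(pos)
        return pos

    def in_target(self, pool: list[TargetInterval]) -> int:
        t = pool[int(self.rng.integers(0, len(pool)))]
        return self._unique(int(self.rng.integers(t.start, t.end + 1)))

    def far_from_targets(self) -> int:
        """In-locus position > pad bases away from every target."""
        locus = self.cfg.linkage_locus
        pad = self.cfg.target_pad_bases
        for _ in range(1000):
            iv = locus.intervals[int(self.rng.integers(0, len(locus.intervals)))]
            pos = int(self.rng.integers(iv.start, iv.end + 1))
            if pos in self.used:
                continue
            if all(
                t.chrom != iv.chrom or t.distance_to(pos) > pad
                for t in self.all_targets
            ):
                self.used.add(pos)
                return pos
        raise SimConfigError("could not place an off-target position")

    def anywhere_chr17(self) -> int:
        return self._unique(int(self.rng.integers(1_000_000, 80_000_000)))


def _rare_freqs(rng: np.random.Generator) -> PopulationFrequencies:
    """Candidate-grade frequencies: database-absent or <= 0.09%."""
    if rng.random() < 0.5:
        return PopulationFrequencies()
    return PopulationFrequencies(esp_percent=round(float(rng.uniform(0.005, 0.09)), 3))


def _background_freqs(cfg: SimConfig, rng: np.random.Generator) -> PopulationFrequencies:
    if rng.random() < cfg.freq_absent_mass:
        return PopulationFrequencies()
    lo, hi = cfg.freq_range_percent
    f = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
    which = int(rng.integers(0, 3))
    vals = [None, None, None]
    vals[which] = round(f, 4)
    return PopulationFrequencies(
        esp_percent=vals[0], kg_percent=vals[1], kg_ceu_percent=vals[2]
    )


def plant_variants(
    families: list[Family],
    cfg: SimConfig,
    targets: Optional[list[TargetInterval]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AnnotatedVariant], dict[tuple[VariantKey, str], GenotypeCall], TruthTable, dict[VariantKey, str]]:
    """Plant candidates, per-class decoys and background variants.

    Returns (variants, sequenced-only genotype map, truth table,
    sanger plan mapping variant key -> {"full","partial","failed"}).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if targets is None:
        raise SimConfigError("capture targets must be provided")
    if not cfg.linkage_locus.intervals:
        raise SimConfigError("linkage locus must be provided")

    pool = _PositionPool(cfg, targets, rng)
    chrom = cfg.linkage_locus.intervals[0].chrom
    truth = TruthTable()
    variants: list[AnnotatedVariant] = []
    genotypes: dict[tuple[VariantKey, str], GenotypeCall] = {}
    sanger_plan: dict[VariantKey, str] = {}
    gene_no = [0]

    eligible = [f for f in families if f.sequenced_affected]
    multi = [f for f in eligible if len(f.sequenced_affected) >= 2]
    if cfg.n_planted_candidates and not eligible:
        raise SimConfigError("no family has a sequenced affected member")

    def next_gene() -> str:
        gene_no[0] += 1
        return f"SIMG{gene_no[0]:03d}"

    def pick(fams: list[Family]) -> Family:
        return fams[int(rng.integers(0, len(fams)))]

    def register(
        v: AnnotatedVariant,
        category: str,
        fate: str,
        fams: list[str],
        pattern: dict[str, dict[str, GenotypeCall]],
        sanger: str,
    ) -> None:
        variants.append(v)
        sanger_plan[v.key] = sanger
        flat: dict[str, str] = {}
        for fid, calls in pattern.items():
            fam = next(f for f in families if f.family_id == fid)
            for m in fam.members:
                call = calls.get(m.individual_id, GenotypeCall.NON_CARRIER)
                flat[m.individual_id] = call.value
                if m.sequenced:
                    genotypes[(v.key, m.individual_id)] = call
        # non-pattern families: explicit non-carriers for sequenced members
        for fam in families:
            if fam.family_id not in pattern:
                for m in fam.members:
                    flat[m.individual_id] = GenotypeCall.NON_CARRIER.value
                    if m.sequenced:
                        genotypes[(v.key, m.individual_id)] = GenotypeCall.NON_CARRIER
        truth.add(TruthRecord(v.key_str, category, fate, fams, flat))

    def candidate_like(
        fam: Family, pos: int, func=FunctionalClass.MISSENSE, freqs=None
    ) -> tuple[AnnotatedVariant, dict]:
        ref, alt = _random_snv(rng)
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
            gene_symbol=next_gene(), functional_class=func,
            freqs=_rare_freqs(rng) if freqs is None else freqs,
            scaled_c_score=round(float(rng.uniform(5, 35)), 1),
        )
        calls = _forced_drop_to(
            fam, rng, [m.individual_id for m in fam.sequenced_affected]
        )
        return v, {fam.family_id: calls}

    # --- planted candidates -------------------------------------------------
    for _ in range(cfg.n_planted_candidates):
        fam = pick(eligible)
        v, pattern = candidate_like(fam, pool.in_target(pool.exonic_in))
        register(v, "planted", PASSED, [fam.family_id], pattern, "full")

    # --- decoys -------------------------------------------------------------
    for _ in range(cfg.decoys_per_class):
        # common_freq: >5% ESP, everything else compliant
        fam = pick(eligible)
        v, pattern = candidate_like(
            fam, pool.in_target(pool.exonic_in),
            freqs=PopulationFrequencies(esp_percent=round(float(rng.uniform(6, 20)), 2)),
        )
        register(v, "decoy:common_freq", "Rare Variant", [fam.family_id], pattern, "full")

        # off_locus: outside the linkage region, on an exonic target
        fam = pick(eligible)
        v, pattern = candidate_like(fam, pool.in_target(pool.exonic_out))
        register(v, "decoy:off_locus", "Linked Locus", [fam.family_id], pattern, "full")

        # off_target: in locus, > pad bases from every capture target
        fam = pick(eligible)
        v, pattern = candidate_like(fam, pool.far_from_targets())
        register(v, "decoy:off_target", "Targeted Region", [fam.family_id], pattern, "full")

        # non_segregating: carried by only some sequenced affected members
        if not multi:
            raise SimConfigError(
                "non_segregating decoys need a family with >= 2 sequenced affected"
            )
        fam = pick(multi)
        ref, alt = _random_snv(rng)
        v = AnnotatedVariant(
            chrom=chrom, pos=pool.in_target(pool.exonic_in),
            ref_allele=ref, alt_allele=alt, gene_symbol=next_gene(),
            functional_class=FunctionalClass.MISSENSE, freqs=_rare_freqs(rng),
            scaled_c_score=round(float(rng.uniform(5, 35)), 1),
        )
        calls = _partial_segregation_drop(fam, rng)
        register(
            v, "decoy:non_segregating", "Family Segregation",
            [fam.family_id], {fam.family_id: calls}, "full",
        )

        # unaffected_only: allele introduced by an unaffected founder
        options = [
            (f, calls)
            for f in eligible
            if (calls := _unaffected_only_calls(f)) is not None
        ]
        if not options:
            raise SimConfigError(
                "no family has a sequenced unaffected member reachable from "
                "an unaffected founder (needed for the unaffected_only decoy)"
            )
        fam, calls = options[int(rng.integers(0, len(options)))]
        ref, alt = _random_snv(rng)
        v = AnnotatedVariant(
            chrom=chrom, pos=pool.in_target(pool.exonic_in),
            ref_allele=ref, alt_allele=alt, gene_symbol=next_gene(),
            functional_class=FunctionalClass.MISSENSE, freqs=_rare_freqs(rng),
            scaled_c_score=round(float(rng.uniform(5, 35)), 1),
        )
        register(
            v, "decoy:unaffected_only", "Family Segregation",
            [fam.family_id], {fam.family_id: calls}, "full",
        )

        # synonymous: survives every initial filter, dropped post-Sanger
        fam = pick(eligible)
        v, pattern = candidate_like(
            fam, pool.in_target(pool.exonic_in), func=FunctionalClass.SYNONYMOUS
        )
        register(
            v, "decoy:synonymous", "Protein Alteration", [fam.family_id], pattern, "full"
        )

        # sanger_partial / sanger_failed: concordance decoys
        if not multi:
            raise SimConfigError(
                "sanger_partial decoys need a family with >= 2 sequenced affected"
            )
        fam = pick(multi)
        v, pattern = candidate_like(fam, pool.in_target(pool.exonic_in))
        register(
            v, "decoy:sanger_partial", "Sanger Verification",
            [fam.family_id], pattern, "partial",
        )
        fam = pick(eligible)
        v, pattern = candidate_like(fam, pool.in_target(pool.exonic_in))
        register(
            v, "decoy:sanger_failed", "Sanger Verification",
            [fam.family_id], pattern, "failed",
        )

    # --- background ---------------------------------------------------------
    func_classes = list(FunctionalClass)
    for _ in range(cfg.background_variant_count):
        ref, alt = _random_snv(rng)
        v = AnnotatedVariant(
            chrom=chrom, pos=pool.anywhere_chr17(),
            ref_allele=ref, alt_allele=alt, gene_symbol=next_gene(),
            functional_class=func_classes[int(rng.integers(0, len(func_classes)))],
            freqs=_background_freqs(cfg, rng),
            scaled_c_score=round(float(rng.uniform(0, 40)), 1)
            if rng.random() < 0.8 else None,
        )
        pattern: dict[str, dict[str, GenotypeCall]] = {}
        for fam in families:
            founders = {
                m.individual_id
                for m in fam.members
                if m.father_id is None and m.mother_id is None
                and rng.random() < 0.15
            }
            pattern[fam.family_id] = gene_drop(fam, rng, founders)
        carrier_sets = {
            fid: {iid for iid, c in calls.items() if c.is_carrier}
            for fid, calls in pattern.items()
        }
        fate = _evaluate_fate(
            v, carrier_sets, families, targets, cfg.linkage_locus,
            default_cgc_genes(), cfg.target_pad_bases, "full",
        )
        register(v, "background", fate, [], pattern, "full")

    return variants, genotypes, truth, sanger_plan


def _unaffected_only_calls(fam: Family) -> Optional[dict[str, GenotypeCall]]:
    """Mendelian carrier pattern touching only unaffected members, or None.

    Prefers a sequenced unaffected founder (married-in or top-couple);
    otherwise a sequenced unaffected child of an unaffected founder, with
    the founder parent introducing the allele.
    """
    by_id = {m.individual_id: m for m in fam.members}
    for m in fam.members:
        if (
            m.sequenced and not m.affected
            and m.father_id is None and m.mother_id is None
        ):
            return {m.individual_id: GenotypeCall.CARRIER_HET}
    for m in fam.members:
        if not (m.sequenced and not m.affected):
            continue
        for pid in (m.father_id, m.mother_id):
            p = by_id.get(pid) if pid else None
            if (
                p is not None and not p.affected
                and p.father_id is None and p.mother_id is None
            ):
                return {
                    p.individual_id: GenotypeCall.CARRIER_HET,
                    m.individual_id: GenotypeCall.CARRIER_HET,
                }
    return None


def make_sanger_observations(
    cohort: Cohort, sanger_plan: dict[VariantKey, str]
) -> list[SangerObservation]:
    """Emit bidirectional read calls for every affected NGS carrier.

    All variants with an affected carrier are interrogated (excluded
    variants are verified too); the plan selects the per-class pattern.
    """
    obs: list[SangerObservation] = []
    for v in cohort.variants:
        plan = sanger_plan.get(v.key, "full")
        carriers = [
            m.individual_id
            for fam in cohort.families
            for m in fam.sequenced_affected
            if cohort.is_carrier(v, m.individual_id)
        ]
        for i, iid in enumerate(carriers):
            if plan == "failed":
                fwd = rev = StrandCall.NO_READ
            elif plan == "partial" and i > 0:
                fwd, rev = StrandCall.CONCORDANT, StrandCall.NO_READ
            else:
                fwd = rev = StrandCall.CONCORDANT
            obs.append(SangerObservation(v.key, iid, fwd, rev))
    return obs


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic cohort, its filter config and truth table."""
    rng = np.random.default_rng(cfg.seed)
    families = generate_pedigrees(cfg, rng)
    targets = make_targets(cfg)
    variants, genotypes, truth, sanger_plan = plant_variants(
        families, cfg, targets=targets, rng=rng
    )
    cohort = Cohort(families=families, variants=variants, genotypes=genotypes)
    observations = make_sanger_observations(cohort, sanger_plan)
    filter_config = FilterConfig(
        linkage_locus=cfg.linkage_locus,
        target_intervals=targets,
        target_pad_bases=cfg.target_pad_bases,
        cgc_genes=default_cgc_genes(),
    )
    return SimResult(cohort, observations, filter_config, truth, cfg)


def write_cohort(result: SimResult, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the simulated cohort as PED/VCF/TSV/BED/JSON text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "cohort.ped",
        "vcf": out / "cohort.vcf",
        "annotations": out / "annotations.tsv",
        "sanger": out / "sanger.tsv",
        "targets": out / "targets.bed",
        "linkage": out / "linkage.bed",
        "truth": out / "truth.json",
    }
    write_pedigree(result.cohort.families, paths["ped"])
    write_vcf(result.cohort, paths["vcf"])
    write_annotations(result.cohort.variants, paths["annotations"])
    write_sanger_observations(result.observations, paths["sanger"])
    write_targets(result.filter_config.target_intervals, paths["targets"])
    write_intervals(result.sim_config.linkage_locus.intervals, paths["linkage"])
    paths["truth"].write_text(result.truth.to_json())
    return paths
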