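import itertools

import pytest

from glioseg.filters import (
    AuditTrail,
    FilterConfig,
    FINAL_MAF_FIELDS,
    INITIAL_MAF_FIELDS,
    audit_percentages,
    family_segregation_filter,
    in_linkage_locus,
    linked_locus_filter,
    maf_filter,
    protein_alteration_filter,
    run_full_pipeline,
    run_initial_stage,
    run_post_sanger_stage,
    targeted_region_filter,
)
from glioseg.model import (
    Cohort,
    Family,
    FunctionalClass,
    GenomicInterval,
    Individual,
    LinkageLocus,
    PopulationFrequencies,
    TargetInterval,
)
from glioseg.sanger import VerificationStatus

from conftest import HET, REF, make_variant


LOCUS = LinkageLocus()


def cfg_with(targets=None, **kw):
    targets = targets or [TargetInterval("17", 40_000_000 - 60, 40_000_000 + 60, exonic=True)]
    return FilterConfig(target_intervals=targets, **kw)


class TestLinkedLocus:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (49_098_662, True),   # inside the first interval
            (34_355_567, True),   # lower boundary, closed
            (34_355_566, False),  # one base below
            (52_135_011, True),   # upper boundary of interval 1
            (53_000_000, False),  # gap between the two intervals
            (54_612_056, True),   # lower boundary of interval 2
            (61_596_549, False),  # one base past interval 2
        ],
    )
    def test_locus_membership(self, pos, expected):
        assert in_linkage_locus(pos, LOCUS, chrom="17") is expected

    def test_cgc_waiver_rescues_off_locus_gene_in_initial_mode_only(self):
        cfg = cfg_with()
        nf1 = make_variant(pos=29_550_000, gene="NF1")
        other = make_variant(pos=29_550_000, gene="ZZZ9", alt="T")
        in_locus = make_variant(pos=49_098_662, gene="SPAG9", alt="T", ref="G")
        assert linked_locus_filter(in_locus, cfg, waive_cgc=True)
        assert linked_locus_filter(nf1, cfg, waive_cgc=True)
        assert not linked_locus_filter(other, cfg, waive_cgc=True)
        # no waiver at the post-Sanger stage
        assert not linked_locus_filter(nf1, cfg, waive_cgc=False)

    def test_no_gene_symbol_outside_locus_drops(self):
        v = make_variant(pos=10_000, gene=None)
        assert not linked_locus_filter(v, cfg_with(), waive_cgc=True)


class TestTargetedRegion:
    def test_padded_distances(self):
        cfg = cfg_with(targets=[TargetInterval("17", 1100, 1200)])
        assert targeted_region_filter(make_variant(pos=1000), cfg, "padded")  # 100 away
        assert targeted_region_filter(make_variant(pos=900), cfg, "padded")  # tie at 200
        assert not targeted_region_filter(make_variant(pos=850), cfg, "padded")  # 250
        assert targeted_region_filter(make_variant(pos=1150), cfg, "padded")  # inside

    def test_cgc_waiver_in_padded_mode(self):
        cfg = cfg_with(targets=[TargetInterval("17", 1100, 1200)])
        brca1 = make_variant(pos=10, gene="BRCA1")
        assert targeted_region_filter(brca1, cfg, "padded", waive_cgc=True)
        assert not targeted_region_filter(brca1, cfg, "padded", waive_cgc=False)

    def test_exonic_mode_ignores_pad_and_nonexonic_targets(self):
        cfg = cfg_with(
            targets=[
                TargetInterval("17", 1100, 1200, exonic=False),
                TargetInterval("17", 2000, 2100, exonic=True),
            ]
        )
        assert not targeted_region_filter(make_variant(pos=1150), cfg, "exonic")
        assert targeted_region_filter(make_variant(pos=2000), cfg, "exonic")
        assert not targeted_region_filter(make_variant(pos=1999), cfg, "exonic")

    def test_empty_targets_rejected(self):
        cfg = cfg_with()
        cfg.target_intervals = []
        with pytest.raises(ValueError):
            targeted_region_filter(make_variant(), cfg, "padded")


class TestMafFilter:
    @pytest.mark.parametrize(
        "freqs,threshold,fields,keep",
        [
            (dict(esp_percent=0.069), 0.1, FINAL_MAF_FIELDS, True),
            (dict(kg_percent=0.09), 0.1, FINAL_MAF_FIELDS, True),
            (dict(), 0.1, FINAL_MAF_FIELDS, True),  # absent everywhere
            (dict(esp_percent=6.0), 5.0, INITIAL_MAF_FIELDS, False),
            (dict(esp_percent=5.0), 5.0, INITIAL_MAF_FIELDS, True),  # strict >
            (dict(esp_percent=0.1), 0.1, FINAL_MAF_FIELDS, True),  # strict >
            (dict(esp_percent=0.2), 0.1, FINAL_MAF_FIELDS, False),
            # overall 1000G frequency is NOT tested by the initial filter
            (dict(kg_percent=50.0), 5.0, INITIAL_MAF_FIELDS, True),
            (dict(kg_ceu_percent=6.0), 5.0, INITIAL_MAF_FIELDS, False),
        ],
    )
    def test_threshold_logic(self, freqs, threshold, fields, keep):
        assert maf_filter(PopulationFrequencies(**freqs), threshold, fields) is keep

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            maf_filter(PopulationFrequencies(), 0.0, FINAL_MAF_FIELDS)


class TestFamilySegregation:
    def _cohort(self, calls):
        fam = Family(
            "F",
            [
                Individual("a1", "F", affected=True, sequenced=True),
                Individual("a2", "F", affected=True, sequenced=True),
                Individual("u1", "F", sequenced=True),
            ],
        )
        v = make_variant()
        genotypes = {(v.key, iid): c for iid, c in calls.items()}
        return v, Cohort(families=[fam], variants=[v], genotypes=genotypes)

    def test_all_affected_carriers_keeps(self):
        v, cohort = self._cohort({"a1": HET, "a2": HET})
        keep, fams = family_segregation_filter(v, cohort)
        assert keep and fams == ["F"]

    def test_partial_affected_carriage_drops(self):
        v, cohort = self._cohort({"a1": HET, "a2": REF})
        assert family_segregation_filter(v, cohort) == (False, [])

    def test_unaffected_only_carriage_drops(self):
        v, cohort = self._cohort({"u1": HET})
        assert family_segregation_filter(v, cohort) == (False, [])

    def test_single_sequenced_affected_carrier_keeps(self):
        fam = Family(
            "K",
            [
                Individual("aff", "K", affected=True, sequenced=True),
                Individual("dead", "K", affected=True, sequenced=False),
            ],
        )
        v = make_variant()
        cohort = Cohort([fam], [v], {(v.key, "aff"): HET})
        assert family_segregation_filter(v, cohort) == (True, ["K"])

    def test_family_without_sequenced_affected_never_segregates(self):
        fam = Family("Z", [Individual("u", "Z", sequenced=True)])
        v = make_variant()
        cohort = Cohort([fam], [v], {(v.key, "u"): HET})
        assert family_segregation_filter(v, cohort) == (False, [])


@pytest.mark.parametrize(
    "func,keep",
    [
        (FunctionalClass.MISSENSE, True),
        (FunctionalClass.NONSENSE, True),
        (FunctionalClass.FRAMESHIFT, True),
        (FunctionalClass.SPLICE, True),
        (FunctionalClass.SYNONYMOUS, False),
        (FunctionalClass.INTRONIC, False),
        (FunctionalClass.UTR, False),
    ],
)
def test_protein_alteration_filter(func, keep):
    assert protein_alteration_filter(make_variant(func=func), cfg_with()) is keep


class TestStagedRunners:
    def test_decoys_attributed_to_their_intended_stage(self, sim_result):
        result = run_full_pipeline(
            sim_result.cohort, sim_result.observations, sim_result.filter_config
        )
        fate = result.combined_fate
        for key, rec in sim_result.truth.records.items():
            if rec.category.startswith("decoy:"):
                chrom, pos, ref, alt = key.split(":")
                assert fate[(chrom, int(pos), ref, alt)] == rec.intended_fate, rec.category

    def test_empty_cohort_gives_zero_count_trail(self):
        fam = Family("F", [Individual("a", "F", affected=True, sequenced=True)])
        cohort = Cohort([fam], [], {})
        survivors, trail = run_initial_stage(cohort, cfg_with())
        assert survivors == []
        assert [(s.variants_in, s.variants_out) for s in trail.stages] == [(0, 0)] * 4

    def test_all_common_variants_dropped_at_rarity_stage(self):
        fam = Family("F", [Individual("a", "F", affected=True, sequenced=True)])
        variants = [
            make_variant(pos=40_000_000 + i, esp=8.0 + i, alt="G", ref="A")
            for i in range(3)
        ]
        cohort = Cohort(
            [fam], variants, {(v.key, "a"): HET for v in variants}
        )
        cfg = cfg_with(targets=[TargetInterval("17", 39_999_000, 40_001_000, exonic=True)])
        survivors, trail = run_initial_stage(cohort, cfg)
        assert survivors == []
        by_name = {s.stage_name: s for s in trail.stages}
        assert by_name["Rare Variant"].variants_in == 3
        assert by_name["Rare Variant"].variants_out == 0

    def test_chain_conservation_each_variant_one_fate(self, sim_result):
        survivors, trail = run_initial_stage(sim_result.cohort, sim_result.filter_config)
        for a, b in zip(trail.stages, trail.stages[1:]):
            assert a.variants_out == b.variants_in
        n_dropped = sum(len(s.dropped_variant_keys) for s in trail.stages)
        assert n_dropped + len(survivors) == len(sim_result.cohort.variants)
        assert len(trail.fate) == len(sim_result.cohort.variants)

    def test_missing_sanger_status_rejected(self, sim_result):
        v = sim_result.cohort.variants[0]
        with pytest.raises(ValueError, match="verification status"):
            run_post_sanger_stage(
                [v], {}, sim_result.cohort, sim_result.filter_config
            )

    def test_post_sanger_survivor_set_order_independent(self, candidate_fixture):
        """The four final predicates commute: survivors are permutation-invariant."""
        fx = candidate_fixture
        cfg = fx.config
        predicates = {
            "locus": lambda v: linked_locus_filter(v, cfg, waive_cgc=False),
            "maf": lambda v: maf_filter(v.freqs, cfg.final_maf_threshold_percent, FINAL_MAF_FIELDS),
            "exome": lambda v: targeted_region_filter(v, cfg, mode="exonic"),
            "protein": lambda v: protein_alteration_filter(v, cfg),
        }
        # make the set non-trivial: shift some positions/classes
        variants = list(fx.cohort.variants)
        variants += [
            make_variant(pos=53_000_001, ref="T", alt="C"),  # off locus
            make_variant(pos=49_098_662, ref="T", alt="C", esp=0.5),  # too common
            make_variant(pos=49_098_662, ref="T", alt="A", func=FunctionalClass.SYNONYMOUS),
        ]
        reference = None
        for order in itertools.permutations(predicates.values()):
            surviving = {
                v.key for v in variants if all(p(v) for p in order)
            }
            if reference is None:
                reference = surviving
            assert surviving == reference

    def test_pipeline_matches_brute_force_predicate_conjunction(self, sim_result):
        """Stage machinery must agree with direct per-variant evaluation."""
        fx = sim_result
        result = run_full_pipeline(fx.cohort, fx.observations, fx.filter_config)
        cfg = fx.filter_config
        from glioseg.filters import verify_batch

        statuses = verify_batch(fx.cohort.variants, fx.observations, fx.cohort)
        brute = set()
        for v in fx.cohort.variants:
            ok = (
                linked_locus_filter(v, cfg, waive_cgc=True)
                and targeted_region_filter(v, cfg, "padded", waive_cgc=True)
                and maf_filter(v.freqs, 5.0, INITIAL_MAF_FIELDS)
                and family_segregation_filter(v, fx.cohort)[0]
                and statuses[v.key] is VerificationStatus.FULLY_VERIFIED
                and linked_locus_filter(v, cfg, waive_cgc=False)
                and maf_filter(v.freqs, 0.1, FINAL_MAF_FIELDS)
                and targeted_region_filter(v, cfg, "exonic")
                and protein_alteration_filter(v, cfg)
            )
            if ok:
                brute.add(v.key)
        assert {v.key for v in result.surviving_variants} == brute


class TestAuditPercentages:
    def _trail(self, pairs):
        trail = AuditTrail()
        variants = [make_variant(pos=i + 1, ref="A", alt="G") for i in range(pairs[0][0])]
        for i, (n_in, n_out) in enumerate(pairs):
            stage_in = variants[:n_in]
            survivors = stage_in[:n_out]
            trail.record_stage(f"s{i}", stage_in, survivors)
            variants = survivors
        return trail

    @pytest.mark.parametrize(
        "n_in,n_out,expected",
        [(539, 278, 51.6), (278, 186, 66.9), (7, 7, 100.0), (3, 1, 33.3)],
    )
    def test_rounding_half_up_one_decimal(self, n_in, n_out, expected):
        trail = self._trail([(n_in, n_out)])
        assert audit_percentages(trail) == [("s0", expected)]

    def test_zero_input_stage_reports_undefined(self):
        trail = self._trail([(5, 0), (0, 0)])
        assert audit_percentages(trail)[1] == ("s1", None)

    def test_empty_trail_rejected(self):
        with pytest.raises(ValueError):
            audit_percentages(AuditTrail())
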