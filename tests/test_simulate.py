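import dataclasses

import numpy as np
import pytest

from glioseg.filters import run_full_pipeline
from glioseg.model import AnnotatedVariant, FunctionalClass, GenotypeCall, PopulationFrequencies
from glioseg.simulate import (
    DECOY_CLASSES,
    SimConfig,
    SimConfigError,
    generate_pedigrees,
    make_sanger_observations,
    make_targets,
    simulate,
    write_cohort,
)


def pipeline_survivors(result):
    res = run_full_pipeline(result.cohort, result.observations, result.filter_config)
    return {v.key_str for v in res.surviving_variants}


class TestPedigrees:
    def test_seed_determinism_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_cohort(simulate(SimConfig(n_families=6, seed=7)), d1)
        p2 = write_cohort(simulate(SimConfig(n_families=6, seed=7)), d2)
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes(), k

    def test_fixed_affected_count_honoured(self):
        fams = generate_pedigrees(SimConfig(n_families=8, n_affected_per_family=2, seed=3))
        for fam in fams:
            assert sum(m.affected for m in fam.members) == 2

    def test_affected_are_blood_relatives(self):
        for fam in generate_pedigrees(SimConfig(n_families=10, seed=5)):
            for m in fam.members:
                if m.affected:
                    # blood members either are founders of the top couple or
                    # have both parents in the pedigree
                    assert (m.father_id is None) == (m.mother_id is None)

    def test_infeasible_affected_count_rejected(self):
        with pytest.raises(SimConfigError, match="affected"):
            generate_pedigrees(SimConfig(n_families=2, pedigree_depth=2,
                                         n_affected_per_family=40, seed=0))

    def test_two_affected_fraction_near_default_mixture(self):
        fams = generate_pedigrees(SimConfig(n_families=200, seed=11))
        frac = np.mean([sum(m.affected for m in f.members) == 2 for f in fams])
        # 99% binomial interval around 0.83 at n=200
        half = 2.576 * np.sqrt(0.83 * 0.17 / 200)
        assert 0.83 - half <= frac <= 0.83 + half


class TestTruthTable:
    def test_planted_count_matches_config(self, sim_result):
        planted = [r for r in sim_result.truth.records.values() if r.category == "planted"]
        assert len(planted) == sim_result.sim_config.n_planted_candidates
        assert all(r.intended_fate == "passed" for r in planted)

    def test_every_variant_has_exactly_one_fate(self, sim_result):
        assert len(sim_result.truth.records) == len(sim_result.cohort.variants)

    def test_all_decoy_classes_present(self, sim_result):
        cats = {r.category for r in sim_result.truth.records.values()}
        assert {f"decoy:{c}" for c in DECOY_CLASSES} <= cats


class TestMendelianConsistency:
    def test_every_carrier_child_has_a_carrier_parent(self, sim_result):
        """Brute-force trio check over the full carrier patterns."""
        members = {
            m.individual_id: m
            for fam in sim_result.cohort.families
            for m in fam.members
        }
        for rec in sim_result.truth.records.values():
            for iid, call in rec.carrier_pattern.items():
                if call == GenotypeCall.NON_CARRIER.value:
                    continue
                m = members[iid]
                if m.father_id is None and m.mother_id is None:
                    continue  # founder introduction
                parent_calls = [
                    rec.carrier_pattern.get(pid, GenotypeCall.NON_CARRIER.value)
                    for pid in (m.father_id, m.mother_id)
                    if pid is not None
                ]
                assert any(
                    c in (GenotypeCall.CARRIER_HET.value, GenotypeCall.CARRIER_HOM.value)
                    for c in parent_calls
                ), f"{rec.variant_key}: carrier {iid} without carrier parent"

    def test_cohort_genotypes_restricted_to_sequenced(self, sim_result):
        sequenced = {m.individual_id for m in sim_result.cohort.sequenced_individuals}
        assert all(iid in sequenced for (_, iid) in sim_result.cohort.genotypes)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_pipeline_recovers_truth_exactly(self, seed):
        result = simulate(SimConfig(seed=seed))
        assert pipeline_survivors(result) == result.truth.passes


@pytest.fixture(scope="module")
def ctx():
    result = simulate(SimConfig(seed=1))
    decoys = {}
    for key, rec in result.truth.records.items():
        if rec.category.startswith("decoy:"):
            decoys.setdefault(rec.category.split(":", 1)[1], (key, rec))
    plan = {}
    for key, rec in result.truth.records.items():
        chrom, pos, ref, alt = key.split(":")
        k = (chrom, int(pos), ref, alt)
        plan[k] = {
            "decoy:sanger_partial": "partial",
            "decoy:sanger_failed": "failed",
        }.get(rec.category, "full")
    return result, decoys, plan


class TestFilterIsolation:
    """Flipping only a decoy's violating attribute makes it pass the pipeline."""

    def _flip_and_run(self, ctx, cls, new_variant=None, make_segregating=False,
                      sanger_full=False):
        import copy

        result, decoys, plan = ctx
        key_str, rec = decoys[cls]
        chrom, pos, ref, alt = key_str.split(":")
        old_key = (chrom, int(pos), ref, alt)

        cohort = copy.deepcopy(result.cohort)
        plan = dict(plan)
        idx = next(i for i, v in enumerate(cohort.variants) if v.key == old_key)
        v = cohort.variants[idx]
        if new_variant is not None:
            cohort.variants[idx] = new_variant
            for (vk, iid) in list(cohort.genotypes):
                if vk == old_key:
                    cohort.genotypes[(new_variant.key, iid)] = cohort.genotypes.pop((vk, iid))
            plan[new_variant.key] = plan.pop(old_key)
            v = new_variant
        if make_segregating:
            fam = cohort.family(rec.planted_family_ids[0])
            for m in fam.sequenced_affected:
                cohort.genotypes[(v.key, m.individual_id)] = GenotypeCall.CARRIER_HET
        if sanger_full:
            plan[v.key] = "full"
        observations = make_sanger_observations(cohort, plan)
        res = run_full_pipeline(cohort, observations, result.filter_config)
        return v.key_str, {x.key_str for x in res.surviving_variants}

    def _clone(self, result, key_str, **changes):
        chrom, pos, ref, alt = key_str.split(":")
        old = next(
            v for v in result.cohort.variants if v.key == (chrom, int(pos), ref, alt)
        )
        return dataclasses.replace(old, **changes)

    def _exonic_pos(self, result):
        cfg = result.filter_config
        used = {v.pos for v in result.cohort.variants}
        for t in cfg.target_intervals:
            if t.exonic and (t.chrom, t.start) in {
                (iv.chrom, p) for iv in cfg.linkage_locus.intervals
                for p in (t.start,) if t.start in iv and t.end in iv
            }:
                for p in range(t.start, t.end + 1):
                    if p not in used:
                        return p
        raise AssertionError("no free exonic in-locus position")

    @pytest.mark.parametrize("cls", DECOY_CLASSES)
    def test_compliant_twin_passes(self, ctx, cls):
        result, decoys, _ = ctx
        key_str, rec = decoys[cls]
        kwargs = {}
        if cls == "common_freq":
            kwargs["new_variant"] = self._clone(result, key_str, freqs=PopulationFrequencies())
        elif cls in ("off_locus", "off_target"):
            kwargs["new_variant"] = self._clone(result, key_str, pos=self._exonic_pos(result))
        elif cls in ("non_segregating", "unaffected_only"):
            kwargs["make_segregating"] = True
        elif cls == "synonymous":
            kwargs["new_variant"] = self._clone(
                result, key_str, functional_class=FunctionalClass.MISSENSE
            )
        elif cls in ("sanger_partial", "sanger_failed"):
            kwargs["sanger_full"] = True
        flipped_key, survivors = self._flip_and_run(ctx, cls, **kwargs)
        assert flipped_key in survivors
        # and the original decoy (all other variants untouched) still fails
        assert result.truth.passes <= survivors | {flipped_key}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("p_sequenced", 1.5), ("pedigree_depth", 5), ("n_families", -1),
         ("n_affected_per_family", 0)],
    )
    def test_bad_config_rejected(self, field, value):
        with pytest.raises(SimConfigError):
            SimConfig(**{field: value})

    def test_targets_required_for_planting(self):
        from glioseg.simulate import plant_variants

        cfg = SimConfig(seed=0)
        fams = generate_pedigrees(cfg)
        with pytest.raises(SimConfigError):
            plant_variants(fams, cfg, targets=None)

    def test_target_design_covers_both_locus_intervals(self):
        cfg = SimConfig(seed=0)
        targets = make_targets(cfg)
        iv1, iv2 = cfg.linkage_locus.intervals
        assert any(t.start in iv1 for t in targets if t.exonic)
        assert any(t.start in iv2 for t in targets if t.exonic)
        assert any(not any(t.start in iv for iv in (iv1, iv2)) for t in targets if t.exonic)
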