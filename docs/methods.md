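# Methods

## Model and assumptions

`glioseg` treats familial variant triage as the conjunction of pure
per-variant predicates applied in a fixed order, with the order only
determining *attribution* (which stage gets credit for a drop), never
the surviving set. The underlying genetic model is a highly penetrant
but not fully penetrant dominant predisposition allele: the segregation
requirement is one-sided — every *sequenced affected* member of at least
one family must carry the allele, while unaffected carriers are
tolerated and merely reported (incomplete penetrance; unaffected carrier
ratios are never filtered on). Zygosity is ignored throughout:
heterozygous and homozygous alternate calls both count as "carrier".

Coordinates are 1-based inclusive (VCF convention); BED input is
converted on read and merged per chromosome. Population frequencies are
stored and compared in percent. Phenotype codes 0/−9 (unknown) are
treated as unaffected for all filtering — the filters reference only the
affected/unaffected strata, and counting an unknown as affected would
let it veto a family's segregation.

## Filter parameters

| parameter | default | units | role |
|---|---|---|---|
| linkage locus | 17:34,355,567–52,135,011 ∪ 54,612,056–61,596,548 | bp, GRCh37 | positional gate (1.7-LOD-drop region) |
| `target_pad_bases` | 200 | bp | proximity pad for the pre-Sanger target filter |
| `initial_maf_threshold_percent` | 5.0 | % | common-variant cut (ESP, 1000G CEU) |
| `final_maf_threshold_percent` | 0.1 | % | very-rare cut (ESP, all 1000G fields) |
| CGC waiver set | 23 chr17 genes | — | exempts Linked Locus + Targeted Region pre-Sanger only |
| protein-altering classes | missense, nonsense, frameshift, splice | — | final consequence filter |

Decisions where the procedure was genuinely open:

* **Threshold strictness.** "Excluded if > x%" is read literally: a
  variant exactly at a threshold is kept, and a missing frequency never
  triggers a drop (absence from the databases is stronger evidence of
  rarity than any recorded value).
* **Which 1000G field at the final cut.** The CEU population is
  specified for the initial 5% filter only; the final 0.1% filter
  conservatively tests every provided 1000G frequency field (maximum
  over fields), so a variant common in any tested panel is removed.
* **CGC waiver scope.** The waiver applies to the two positional filters
  of the initial stage only; the final Linked Locus filter has no
  waiver, so the final list always lies inside the linkage region.
* **±200 bp rule.** Distance is the gap in bases to the nearest target
  endpoint (0 inside); a tie at exactly 200 is kept.
* **Exonic targets.** Capture designs rarely publish an "exonic" subset,
  so the exonic flag is an input column on the target BED (4th column
  `exonic`), not an inference.
* **Sanger decision rule.** Fully verified requires both strands
  concordant in *every* expected affected carrier; at least one
  fully-concordant individual gives partial validation. The remaining
  case — reads present but no individual bidirectionally concordant
  (e.g. discordant calls) — is folded into `design_failed`, making that
  status the catch-all for "not even partially validated". Quality-failed
  traces are expected upstream as no-read; unaffected relatives' reads
  never affect the status.
* **Ranking.** Descending scaled C-score with ascending position as the
  tie-break (the published ordering is compatible but silent on ties);
  unscored variants rank last rather than being excluded, since score
  availability is an annotation property, not a filter.
* **Audit arithmetic.** Percent retained is 100·out/in rounded half-up
  to one decimal (539→278 gives 51.6); a zero-input stage reports an
  undefined marker instead of raising.

## Synthetic cohorts

The generator (`glioseg.simulate`) emulates the features the pipeline's
correctness depends on, not sequence-level realism:

* **Pedigrees** — 2–4 generations descending from one founder couple
  with married-in spouses; affected statuses assigned to blood members
  with a 83%/17% two-vs-three+ mixture per family; sequenced flags
  Bernoulli(0.85), with one affected forced sequenced in a 20/23
  fraction of families (elsewhere the affected members' specimens
  failed, mirroring excluded probands).
* **Transmission** — planted candidates are introduced in a founder and
  gene-dropped (transmission probability 1/2 per meiosis), with the
  lineage paths to the target carriers forced so that all sequenced
  affected members of the chosen family carry the allele; every carrier
  pattern is Mendelian-consistent by construction.
* **Decoys** — one class per predicate (common frequency, off-locus,
  off-target, non-segregating, unaffected-only, synonymous, partial and
  failed Sanger concordance), each violating exactly its own predicate,
  so a planted-truth run also checks stage attribution. Excluded
  variants still receive Sanger reads, which keeps single-attribute
  flips testable.
* **Background** — positions uniform over the chromosome, frequencies
  from a mixture of a 0.4 point mass at database-absent and a
  log-uniform spectrum over 0.01–20%, genotypes gene-dropped from random
  founder carriers. Their intended fates are scored by a small
  self-contained evaluator kept deliberately independent of
  `glioseg.filters`, so generator truth and pipeline output are two
  routes to the same answer.

Not emulated: linkage disequilibrium and haplotype structure, mutation
and genotyping error, sex-linked inheritance (one pseudo-autosomal
diploid chromosome model), raw reads or chromatograms. Passing the
planted-truth tests therefore demonstrates the *logic* of the triage on
cohorts with this structure, not robustness to caller artefacts or
pedigree errors in real data.

## Problem sizes and numerics

Default simulations use 12 families, 4 planted candidates, 1 decoy per
class and 40 background variants (52 variants total) — large enough
that every stage drops something, small enough that the end-to-end
recovery property is checked across 20 seeds in well under a second.
The mixture-fraction check uses 200 families against a 99% binomial
interval around 0.83. The packaged fixtures are fixed-size: 20 families
/ 58 affected individuals, and 21 candidate variants whose carrier
ratios are inflated into explicit per-individual genotypes.

Degenerate inputs: empty cohorts produce zero-count audit trails;
empty candidate lists produce reports with zero counts; a variant
reaching the post-Sanger stage without a verification status is an
error, as are genotype entries for unsequenced individuals, dangling
parent links, and annotation key collisions.

## Known limitations

* The audit trail attributes each drop to the first failing stage; a
  variant violating several predicates is counted once.
* The published upstream totals (thousands of annotated calls from raw
  sequencing) depend on primary data the package does not consume; the
  pipeline starts from an annotated VCF.
* `classify_sharing` is defined only for final-list records (affected
  numerator = denominator) and rejects anything else.
* The generator plants at most one candidate per variant key and keeps
  gene symbols unique, so multi-family gene recurrence is exercised by
  the packaged candidate fixture, not the simulator.
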