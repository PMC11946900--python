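# Methods

## Mutation timing relative to whole-genome doubling

### Model

A whole-genome doubling (WGD) duplicates every chromosome, and with it
every somatic mutation present in the doubled cell. In a lineage that has
undergone `k` doublings, a mutation that predates the first doubling lies
on every copy of its parental allele (multiplicity `2^k` absent later
loss), while a mutation acquired afterwards lies on a single copy. Timing
therefore reduces to recovering the variant's integer copy-number state and
deciding which parental allele it tracks.

Given VAF `f`, purity `ρ` and local total copy number `n_T`, the mutant
copy load per cancer cell is obtained by inverting the standard admixture
relation for a diploid normal contaminant:

    n_mut = f · (ρ·n_T + 2(1 − ρ)) / ρ

This is the product of multiplicity and cancer-cell fraction; for a clonal
variant it estimates multiplicity directly. The state is rounded to the
nearest integer (half away from zero, to avoid directional bias) and
clamped to `[1, n_T]`, since a detected variant occupies at least one copy
in the cells carrying it.

Allele tracking: with LOH (minor copy number 0) the variant can only sit
on the major allele; a state exceeding the minor copy number likewise
forces the major allele; otherwise the variant is assumed on the minor
allele. A tracked allele with a single copy carries no timing information
and the variant is "unclear". By default only the *tracked* allele must
have ≥ 2 copies; a stricter mode (`single_copy_rule="either"`) also refuses
segments that retain any single-copy allele, because the prose rule this
implements is ambiguous between the two readings. The default was chosen
as the less conservative reading that still never calls "pre" off a
single-copy allele; the alternative remains selectable rather than
silently discarded.

Classification on a once-doubled segment: state ≥ 2 ⇒ pre-WGD, state 1 ⇒
post-WGD. With two doublings, timing is relative to the **first** event:
only state ≥ 4 is confidently pre, state 1 is post, and states 2–3 are
unclear because a variant acquired between the two doublings also reaches
2 copies. We deliberately do not require the pre-WGD state to equal the
tracked allele's full copy count in amplified segments (e.g. 2 of 4 after
independent gains); state ≥ 2 on a multi-copy allele is accepted as pre.
This is the permissive reading; the exhaustive-enumeration oracle test
pins the implemented rule rather than any unstated intent.

### Confidence handling

Read-count noise is absorbed by a two-sided Wilson score interval with
continuity correction on the VAF (the interval reported by a standard
two-sided one-sample proportion test; R's `prop.test` produces the same
bounds except when its Yates cap engages at the null). The lower limit
yields the *minimum* state — guarding against false pre-WGD calls — and
the upper limit the *maximum* state, guarding against false post-WGD
calls. If the two limits classify differently the call is "unclear". This
makes the caller monotone in interval width: widening the interval can
only move a call toward unclear, never flip pre ↔ post (property-tested).

Multi-region driver timing uses only the upper-limit state in each doubled
region (avoiding false post-WGD categorization), aggregated with the
precedence any-pre > all-post > unclear. Where WGD is subclonal — some
regions doubled, others not — presence of the variant in an undoubled
region forces a pre-WGD call: the mutation must predate a doubling its
lineage never experienced. The full precedence including the override is a
package choice; only the override and the upper-limit rule are dictated by
the method's conservativeness rationale.

Variants overlapping no copy-number segment, or segments with zero tumor
copies, are reported "unclear" with a reason code rather than dropped;
regions annotated with no WGD return "non_wgd".

Defaults: confidence 0.95; variant positions are 1-based, segments 0-based
half-open (BED), with the overlap test converting explicitly.

## Clonality and persistence analyses

Tumor-level clonality here is a deliberately simple stand-in for full
phylogenetic reconstruction (out of scope): a variant is clonal iff it is
present (`alt_count ≥ 2`, configurable — a guard against single-read
artifacts) in every sequenced region and its cancer-cell fraction's upper
confidence bound reaches 0.9 (configurable) in each. The CCF transform
divides the copy load by the point-estimate multiplicity; its upper bound
propagates the Wilson upper VAF limit through the same transform. At least
two regions are required.

Region-level summaries report, per region, the proportion of that region's
pre-WGD-classified mutations that are tumor-clonal, with cohort median and
IQR; regions with no pre-WGD calls are excluded and counted. Metastatic
persistence restricts to variants present in every primary region and
compares, between timing classes, the fraction present in *all*
metastases, with a 2×2 Fisher exact test. Unclear-timed variants are
excluded from both numerator and denominator of timing-stratified
contrasts — they form their own category, not noise to be apportioned.
The two-sided Fisher P is the exact hypergeometric convention (sum of
point probabilities ≤ the observed table's), cross-checked in tests
against exact-rational enumeration.

## ctDNA cluster tracking

Plasma variants are grouped by their assigned phylogenetic cluster and
summarised per timepoint by the arithmetic mean AF over tracked variants.
Variants assayed but yielding zero reads count as AF 0; variants not
assayed at a timepoint are excluded from that mean — a negative assay is
evidence, a missing assay is not. Depth-weighted means are available as an
option; the unweighted mean is the default because panel depths are
near-uniform by design and the unweighted mean keeps each tracked variant's
vote equal. A cluster is "detected" when ≥ 2 variants carry ≥ 2 mutant
reads (both thresholds explicit parameters — no canonical rule exists).

## TCR expansion calling

Each sample is reduced to its 3,000 most abundant CDR3B clones; where
several clones tie at the rank-3,000 count, the whole tie group is kept or
dropped together, whichever leaves the clone number closer to 3,000. Every
clone in the union of test and control then gets a 2×2 table (clone count
vs remaining reads, test vs control), a two-sided Fisher exact P, a sample
odds ratio (infinite when the control count is zero — expansion from
absence is the assay's canonical positive), and a Benjamini–Hochberg Q
across all tested clones. Significance requires OR > 10, Q < 0.01, test
count ≥ 500 and enrichment in the test direction; thresholds are
parameters, and the min-copies threshold sweep reuses one set of P/Q
values, making its counts monotone by construction. Q values are computed
per test/control pair (per condition); pooling across conditions at a
timepoint would change only the BH denominator and is left to the caller
by passing merged inputs. An optional cross-condition uniqueness filter
(clone must not reach significance under any other peptide) can be layered
on by intersecting call sets; the default is control-only, which is the
criterion the statistics define.

Fold changes in detected-clone numbers use the zero-baseline convention
`n_post / max(n_pre, 1)`, so 22 clones against an undetected baseline
report 22.

## The simulator

The generator emulates the sampling design the analyses assume — it is
fixture engineering, kept strictly apart from the inference code.

* **Clone tree and mixtures.** A truncal root plus `n_subclones` (default
  3) clones with random parents. Per region, each subclone's CCF is its
  parent's times a mixture draw: absent (p = 0.35), a regional sweep
  equal to the parent's CCF (p = 0.2) — the generator of
  illusion-of-clonality cases — or uniform(0.1, 0.9) otherwise; sibling
  sums are rescaled so nested populations stay consistent.
* **WGD.** A tumor is doubled with probability 0.76 and, if doubled,
  carries a subclonal WGD with probability 0.19 — both cohort frequencies
  for NSCLC. A truncal doubling doubles every region (second truncal
  doubling with probability 0.14, the cohort's two-event region share);
  a subclonal doubling is attached to one subclone, which is forced to
  sweep a proper subset of regions (those become the doubled regions).
  Mutations ancestral to the carrier are true pre-WGD — the source of
  pre-WGD-but-tumor-subclonal mutations that depress region-level
  clonality in subclonal-WGD tumors.
* **Mutations.** 60% truncal by default; truncal mutations in doubled
  tumors are pre-WGD with probability 0.55. Multiplicity equals the
  carrying allele's copy number for pre-WGD mutations in doubled regions,
  1 otherwise.
* **Copy number.** One segment per autosomal chromosome arm (arm-level
  events dominate the narrative cases this emulates); baseline 1+1,
  doubled 2+2 (or 4+4), with pre-WGD LOH on a fraction 0.2 of arms giving
  2+0 after doubling.
* **Reads.** Depth is Poisson around `mean_depth` (default 400, WES-like)
  with floor 1; alt counts are Binomial(depth, expected VAF) with
  expected VAF = multiplicity × CCF × ρ / (ρ·n_T + 2(1−ρ)).
* **Metastases.** Each founded by one sampled clone (variants private to
  non-ancestral branches absent). Chromosomal instability: per arm, one
  copy of one allele is lost with probability 0.3 and an entire allele
  with probability 0.02 — so single-copy (post-WGD) variants are lost far
  more readily than multi-copy pre-WGD ones.
* **Plasma.** A variant's expected plasma AF is the sum over carrying
  clones of shedding × multiplicity / 2, sampled binomially at the panel
  depth (default 2000×).
* **Repertoires.** Background clone frequencies follow a Zipf power law
  (exponent 1.5), reproducing the rank-abundance shape of real repertoires
  without fitting any dataset; test and control share frequencies and
  differ only by multinomial sampling; spiked clones are overwritten with
  specified counts.

What the simulator does **not** model: sequence-level reads, mutational
signatures, phasing, subclonal copy-number evolution within primary
regions, sequencing artifacts, or contamination. Passing tests therefore
demonstrate correctness of the *procedures* under the stated generative
assumptions, not performance on real sequencing data, where purity and
copy-number estimation error dominate.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configs give byte-identical outputs,
and the acceptance script splits its master seed with `SeedSequence`. The
shipped analyses use desk-scale sizes chosen to make binomial error small
relative to the contrasts measured: timing recovery on 20 tumors × 2,000
mutations × 4 regions at depth 400 and purity U(0.5, 0.8); cohort
contrasts on 30 tumors at the default conditions above; the expansion
caller on 3,000-clone, 100,000-read repertoires over 20 seeds.

## Known limitations

* Purity, WGD status and copy number are consumed as annotations, never
  inferred; errors in them propagate directly into timing calls.
* The two-WGD "unclear band" (states 2–3) is conservative by design;
  mutations between the two doublings are never recovered as a class.
* The clonality stand-in requires ubiquitous presence; low-purity regions
  can therefore deflate clonal calls — the cohort analyses assume regions
  of adequate purity, as their upstream filters would enforce.
* Simulated metastasis loss acts at arm scale; focal losses would weaken
  the pre/post persistence contrast less than the defaults suggest.
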