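# Methods

dosagescope implements an analysis of human copy number variant (CNV)
pathogenicity built on the premise that pathogenic CNVs act through the
dosage sensitivity of the genes they contain. The pipeline has five
scientific components — region/peak detection, gene dosage classification,
mammalian copy-number conservation scoring, a location-randomization null,
and an enrichment battery — plus a synthetic-data generator that stands in
for the dbVar/Ensembl-style inputs.

## Input model and coordinates

CNV calls are autosomal intervals with a type (gain/loss) and a clinical
interpretation (benign/pathogenic). Two ingestion filters are applied: a
minimum call length of 50 bp (the smallest call the source data admit) and
a maximum of one tenth of the carrying chromosome, because near-chromosome
calls inflate gene content and confound downstream gene-level statistics.
Only the two literal interpretation labels are accepted; intermediate
labels such as "likely benign" must be resolved upstream, since any mapping
we chose for them would be arbitrary.

All coordinates are 0-based half-open internally; the dbVar-style dialect
(1-based inclusive) is converted at the file boundary and BED output is
native. GRCh37 autosome lengths are bundled so genome fractions need no
download; the genome-fraction denominator is the summed autosome length,
consistent with the autosomal-only scope.

## CNVRs, coverage and peak regions

CNVs of one interpretation are merged into CNV regions (CNVRs): maximal
overlap-connected components, with abutting (end == start) calls merged —
the default behaviour of standard interval-merge tooling. Gains and losses
can be merged jointly ("grouped") or separately, since duplication and
deletion may be pathogenic through different mechanisms.

Coverage over a CNVR is the step function counting overlapping member
CNVs. A *peak region* is a maximal constant-depth plateau whose two
neighbouring depths are both strictly lower, with depth taken as zero
beyond the CNVR ends. This makes the definition unique and
order-independent, guarantees at least one peak per CNVR, and reduces to
"the whole CNV" for single-member regions, so rare but real calls are not
discarded. Strictly-greater (rather than greater-or-equal) comparison at
plateau boundaries is a deliberate choice: with greater-or-equal, two
adjacent plateaus could both qualify despite one dominating the other.
Benign CNVs are normally analysed whole — if the call is benign there is no
reason to presume an internal critical region — and their peak refinement
is computed only for comparison tables.

## Gene dosage classes

A gene intersects an interval when one or more bases overlap, strand
ignored. Class membership is evaluated against four strata: full benign
gain CNVs, full benign loss CNVs, pathogenic gain *peak regions* and
pathogenic loss *peak regions*. The label is a pure function of the four
booleans:

* only benign → **B**; only pathogenic → **P**;
* benign and pathogenic of the same type (gain∧gain or loss∧loss),
  regardless of other memberships → **X** (passenger);
* exactly benign-loss + pathogenic-gain → **BL_PG**; exactly benign-gain +
  pathogenic-loss → **BG_PL** (the haploinsufficiency-like pattern);
* no membership → unclassified.

The same-type rule dominates the cross-type pairs: any third membership
added to a cross-type pair necessarily creates a same-type pair, so BL_PG
and BG_PL are exactly the "nothing else" combinations. The full 16-row
truth table is checked against an independently written oracle in the test
suite.

A pathogenic region whose overlap contains exactly one Class P gene yields
a *solitary* call — the single candidate causative gene for that region.
Per-CNV annotation fractions (e.g. the proportion of overlapped genes that
are developmental) are undefined for gene-empty CNVs and excluded from
medians rather than scored zero, because a proportion over zero genes has
no value.

## Mammalian copy-number conservation

For each human gene inferred present in the mammalian common ancestor, the
orthology status in 13 mammalian genomes (cow, marmoset, dog, horse, cat,
gorilla, macaque, mouse, rabbit, sheep, chimpanzee, rat, pig) is tallied:
one-to-one = unchanged, one-to-many = duplicated, no orthologue = presumed
loss. A gene is *conserved* when unchanged in all 13. Non-ancestral genes
are excluded from scoring (their absence elsewhere is not evidence of
loss) but retained for benign-CNVR enrichment comparisons.

Genes duplicated on the human lineage since the mammalian divergence are
first grouped into single ancestral units, whose ancestral copy number of
one is compared with each species. Because the profiles carry statuses and
not orthologue identities, a group's per-species status is aggregated by
severity: any member one-to-many → duplicated; else any member one-to-one
→ unchanged (the members are taken to share that single orthologue, the
typical Compara situation for recent in-paralogues); else missing. Residual
many-to-many statuses after grouping are rejected as an input error — the
three-way scheme admits no fourth state. Per-species independence is
assumed when combining statuses within a group.

## Location-randomization null

The null keeps each CNV's chromosome, length, type and interpretation and
redraws its start uniformly over the placements that fit on its
chromosome. Randomization is within-chromosome because cross-chromosome
placement would confound chromosome-level gene density; placed CNVs may
overlap one another; assembly gaps and centromeres are not excluded (a
documented limitation — the synthetic genomes have none, and on real data
the null is correspondingly slightly liberal in gap-rich regions). The
permutation summary reports the observed statistic, the null mean/sd/max,
the normal-approximation Z and an add-one empirical p,
p = (1 + #{null ≥ observed}) / (n_reps + 1), which can never be zero; the
upper-tail normal p is also emitted for comparison with Z-based reporting.
Identical seeds reproduce draws exactly.

## Enrichment battery

Pearson chi-square is used without continuity correction — the ±2
adjusted-residual convention presumes the uncorrected form — with the
adjusted residual (obs−exp)/sqrt(exp·(1−row/N)·(1−col/N)) flagging driving
cells. Rank comparisons use the two-sided Mann–Whitney U with tie-corrected
normal approximation; scale differences across classes use the
Fligner–Killeen test. Term enrichment is an upper-tail hypergeometric
against a caller-supplied background (e.g. all genes within full pathogenic
CNVRs), Bonferroni-corrected over the number of terms actually tested; the
family size m is echoed in every output so the correction is auditable.
These classical tests are delegated to scipy behind the module surface;
the test suite verifies them against independent direct-formula
evaluations to 1e-8.

## Synthetic data

A single latent `dosage_sensitive` boolean per gene drives every signal
the analysis is meant to recover. Defaults (the study conditions for the
recovery tests): 4 chromosomes × 30 Mb; 2,000 non-overlapping 20 kb genes;
20% dosage sensitive; developmental flag at 0.50/0.12
(sensitive/neutral), protein-complex 0.45/0.20, ohnologue 0.45/0.25;
loss-of-function-intolerance scores Beta(2, 1.2) vs Beta(0.5, 5);
expression lognormal with median 20 vs 10 RPKM; 90% of genes ancestral.
Orthology changes occur per species with probability q_sensitive = 0.02 vs
q_neutral = 0.15, split evenly between duplication and loss. CNV strata:
400 benign (200 gain + 200 loss, lognormal median 30 kb) and 200
pathogenic (100 + 100, median 200 kb, σ = 0.8) — the 2:1 count ratio and
the order-of-magnitude length excess of pathogenic calls mirror clinical
call sets. Pathogenic CNVs are anchored onto a random sensitive gene with
probability 0.8; benign CNVs are rejection-placed to avoid all sensitive
genes with probability 0.8. Lengths are truncated to [50 bp, 0.1 ×
chromosome].

The generator emulates the *statistical structure* of the real inputs, not
their biology: no gene overlap or clustering, no CNV hotspots or
recombination structure, no assembly gaps, uniform gene placement, and
independence across species in the orthology model. Passing recovery tests
therefore demonstrate that the machinery detects the encoded signals at
realistic effect sizes and scales — not that the real-genome magnitudes
would be reproduced.

Problem sizes in the test suite and acceptance script (2,000 genes, 600
CNVs, 1,000 permutation repetitions, 100 null-condition replicate runs)
were chosen as the smallest scales at which the encoded effects are
comfortably detectable; they run in seconds to a few minutes on one core.

## Numerical and degenerate-input choices

* Zero-spread permutation nulls: Z is NaN and flagged, never infinite.
* Mann–Whitney with all values identical across both samples returns p = 1.
* Fligner–Killeen with every group degenerate raises; chi-square with a
  zero marginal raises.
* Region-overlap fractions are undefined (raised) for an empty first set.
* Ties in region ids are broken by (chromosome, start, end, id) sorting,
  making every output deterministic and input-order-independent.

## Known limitations

* The pipeline consumes pre-joined flat tables; reproducing the joins
  against live genome resources (annotation, expression, constraint
  scores) is out of scope, as is orthology inference itself.
* The paralogue-grouping severity rule is an approximation forced by
  status-only input; with orthologue identities one could count distinct
  orthologues per species exactly.
* The randomization null does not mask assembly gaps and does not preserve
  inter-CNV spacing.
* Conserved-synteny inspection of individual disease loci (manual,
  figure-driven in the original analysis style) is not implemented; the
  per-gene conservation counts that would feed it are.
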