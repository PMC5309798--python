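# dosagescope

Analysis pipeline for the role of gene dosage sensitivity in human copy
number variant (CNV) pathogenicity.

Clinically interpreted CNVs — benign or pathogenic, gains or losses — are
large and gene-rich, and typically only a subset of the genes they cover
drives the phenotype. dosagescope narrows pathogenic CNVs to their
recurrently affected cores, classifies genes by the pattern of CNVs that
overlap them, and asks whether the candidate dosage-sensitive genes carry
independent evolutionary evidence of dosage constraint: copy-number
conservation across 13 mammalian genomes. It is a library first (importable
API plus `examples/` scripts), with a thin `dosagescope` CLI for shell use.

## What it computes

* **CNVRs and peak regions.** Overlap-connected CNVs of one clinical
  interpretation merge into CNV regions (CNVRs). Within a CNVR, coverage
  (the number of member CNVs over each base) is a step function; a *peak
  region* is any maximal constant-depth plateau strictly higher than both
  flanking depths (zero outside the CNVR). A single-CNV region is its own
  depth-1 peak, so rare calls survive refinement.
* **Dosage classes.** With full benign CNVs and pathogenic *peak regions*
  as the four strata (gain/loss × benign/pathogenic), each gene gets a
  label: **Class B** (benign only), **Class P** (pathogenic only — the
  dosage-sensitivity candidates), **Class X** (same-type benign +
  pathogenic: passengers), **BL/PG** and **BG/PL** (the cross-type
  patterns; BG/PL is the classic haploinsufficiency signature). Peaks whose
  overlap contains exactly one Class P gene yield *solitary* candidate
  disease genes.
* **Conservation scoring.** Per ancestral human gene, the orthology status
  in 13 mammals is tallied as unchanged (one-to-one), duplicated
  (one-to-many) or missing; *conserved* means unchanged in all 13 —
  n_unchanged = 13. Recent human in-paralogues are grouped into one
  ancestral unit first.
* **Location-randomization null.** CNV starts are redrawn uniformly
  within their chromosome, preserving length and count; the observed
  statistic (e.g. the fraction of pathogenic CNVs containing a
  developmental gene) is compared with the permutation null via
  Z = (obs − mean)/sd and an add-one empirical p.
* **Enrichment battery.** Per-class contrasts via Pearson χ² with
  adjusted residuals, two-sided Mann–Whitney U, Fligner–Killeen scale
  test, and upper-tail hypergeometric term enrichment with a custom
  background, all Bonferroni-corrected with the family size echoed.

A synthetic-data generator produces genomes, gene tables, 13-species
orthology and CNV strata with the statistical structure the analysis
assumes (a latent dosage-sensitive gene class that pathogenic CNVs target
and benign CNVs avoid), so the full pipeline is testable without any
downloads. See `docs/methods.md` for the model details and limitations.

## Worked example

Merging four pathogenic deletion calls and finding the recurrent core
(`examples/01_regions_and_peaks.py`):

```
CNVR p_cnvr_loss_0001: 1:10000-80000 (3 CNVs)
  coverage: [10000-25000)x1 [25000-30000)x2 [30000-60000)x3 [60000-70000)x2 [70000-80000)x1
  peak p_cnvr_loss_0001_peak1: [30000-60000) depth 3
CNVR p_cnvr_loss_0002: 1:120000-150000 (1 CNVs)
  coverage: [120000-150000)x1
  peak p_cnvr_loss_0002_peak1: [120000-150000) depth 1
```

Three overlapping case deletions share the [30000,60000) core — that
plateau of coverage 3 is the peak region, the best place to look for the
causative gene. The isolated fourth call keeps its whole extent as a
depth-1 peak.

Testing developmental-gene containment against the randomization null on a
simulated data set (`examples/04_randomization_null.py`):

```
observed: 68.5% of 200 pathogenic CNVs contain a developmental gene
null:     mean 54.4%, max over 1000 randomizations 64.5%
Z = 4.5, empirical p = 0.000999
```

The observed fraction beats every one of 1,000 length- and
chromosome-matched randomizations (Z = 4.5): the excess of developmental
genes in pathogenic CNVs is not a length artefact.

The other scripts in `examples/` cover dosage-class assignment with
solitary calls, conservation scoring with paralogue grouping, and the
end-to-end pipeline (`run_pipeline`), which writes CNVR/peak BEDs, the
per-gene class table, conservation summaries, the enrichment battery and a
manifest echoing every tunable and seed.

## Command line

```sh
dosagescope simulate --seed 3 --out sim/            # synthetic input tables
dosagescope all --cnvs sim/cnvs.tsv --genes sim/genes.tsv \
    --orthology sim/orthology.tsv --build sim/build.tsv \
    --dialect bed_like --reps 1000 --seed 3 --out run/
dosagescope convert calls.tsv --dialect dbvar_tsv --out calls.bed
```

`dosagescope all` (and the per-stage aliases `regions`, `peaks`,
`classify`, `conserve`, `randomize`, `enrich`) runs the pipeline and
prints the summary JSON.

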