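# vus-triage

Variant triage for spinocerebellar-ataxia (SCA) gene panels.

Diagnostic panel sequencing of SCA genes finds many variants of uncertain
significance (VUS) for every pathogenic hit, and only a handful can realistically
be followed up with segregation studies, protein modeling or functional assays.
This package implements, as a tested and reusable pipeline, a triage procedure
for deciding *which* VUSes deserve that effort and for integrating the follow-up
results back into the classification:

1. **QC filters** — exclude calls with read depth < 20 and variants with
   population minor allele frequency (MAF) > 0.1%.
2. **Five-tier classification** (B / LB / VUS / LP / P) by combining weighted
   ACMG/AMP evidence codes via a data-driven rule table, with a curated
   literature lookup taking precedence.
3. **Pathogenicity score** — six in-silico predictors (SIFT, PolyPhen-2,
   MutationTaster, AlignGVGD, PhyloP, Grantham distance) each normalized to a
   unit score *s*ᵢ ∈ [0,1] (1 = pathogenic) and summed:
   *S* = Σᵢ *s*ᵢ ∈ [0, 6].
4. **VUS sub-classification** for follow-up priority:
   * VUS-low: *S* < 3
   * VUS-semi-high: *S* ≥ 3 and present in gnomAD with MAF < 0.1%
   * VUS-high: *S* ≥ 3 and absent from gnomAD
   * VUS-splice: no protein-level score, but ≥ 3 of 4 splice predictors
     (NNsplice, MaxEntScan, GeneSplicer, SpliceSiteFinder-like) agree on a
     ≥ 10% relative WT→variant score change in the same direction; Human
     Splicing Finder consensus values (0–100) verify predicted loss/gain, and
     minigene-assay arithmetic (fragment sizes, frameshift from skipped exon
     length mod 3) models the wet-lab readout.
5. **Reclassification** — a VUS is promoted to LP when it co-segregates with
   disease or a functional test indicates pathogenicity; protein modeling alone
   never promotes, and benign-direction follow-up never demotes below VUS.
6. **Reporting** — unique-variant tier/subclass counts, per-gene distribution,
   and diagnostic yield (percent of patients carrying ≥ 1 P/LP variant,
   truncated to the printed precision).

A synthetic-cohort generator (`vus_triage.simulate`) emulates the cohort
structure this procedure was developed on — 368 patients pooled four per
sequencing pool, pool failures, realistic tier/subclass mixtures,
class-conditional predictor scores, gnomAD presence and sparse follow-up
evidence — with ground-truth labels in a separate `truth_*` column namespace,
so every stage is testable without access to patient data.

## Worked example

The packaged fixtures transcribe the three result tables of the study cohort
(20 P/LP variants, 39 prioritized VUSes, 13 follow-up outcomes). Re-running the
whole pipeline on them:

```sh
$ vus-triage reproduce-paper --out out/
tiers: P=15 LP=5 VUS=39 LB=0
VUS subclasses: low=0 semi_high=23 high=12 splice=4
followed up: 13; reclassified to LP: 4
diagnostic yield: 6.3% -> 7.4% (+1.1)
```

Reading: routine classification yields 15 pathogenic and 5 likely-pathogenic
variants, diagnosing 22 of 348 patients (6.3%). The subclass tree prioritizes
39 VUSes (23 semi-high, 12 high, 4 splice); 13 could be followed up, and the
evidence-integration rule promotes 4 of them to LP, raising the diagnostic
yield to 7.4% (+1.1 percentage points). The same flow is available in code via
`vus_triage.reproduce_study()`, and on your own tables via
`vus-triage run --variants cohort.tsv --evidence followup.tsv --out out/`.

Synthetic cohorts:

```sh
vus-triage simulate --seed 7 --out sim/          # with ground truth
vus-triage simulate --seed 7 --out sim/ --blind  # observables only
```

## Layout

```
src/vus_triage/
  domain.py      data model, minimal cDNA-coordinate parsing
  cohort_io.py   TSV/VCF reading, packaged fixtures, report serialization
  filters.py     depth and frequency exclusion filters
  acmg.py        evidence-combination rule engine + literature lookup
  scoring.py     predictor normalization and the 0-6 pathogenicity score
  subclass.py    VUS-low / -semi-high / -high / -splice decision tree
  splicing.py    splice consensus, HSF verification, minigene arithmetic
  reclassify.py  follow-up evidence integration
  report.py      counting and diagnostic-yield arithmetic
  simulate.py    synthetic cohorts with ground truth
  cli.py         vus-triage run | reproduce-paper | simulate
```

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
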