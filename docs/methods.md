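# Methods

This note documents the models, rules and defaults the package implements,
the choices made where the procedure it encodes left the design open, and
what the synthetic-data tests do and do not demonstrate.

## The triage procedure

The pipeline operates on *observed variants*: one record per unique variant
(transcript + cDNA notation), carrying the set of patients in which it was
seen. Counting conventions follow diagnostic reporting practice: tier and
subclass counts are over unique variants; diagnostic yield is over patients
(a patient is diagnosed when carrying at least one P/LP variant).

### QC filters

Two exclusion filters run before classification, with boundary semantics
chosen to match the stated thresholds exactly:

* **Depth**: calls with read depth < 20 are dropped; depth exactly 20 is
  retained. Depth is per patient-variant observation (pooled sequencing is
  assumed to be deconvolved upstream; the simulator emits per-patient depths).
* **Frequency**: variants with population MAF strictly greater than 0.1% are
  dropped; exactly 0.1% is retained, and absence from the database retains
  the variant. MAF is computed as allele_count / allele_number without
  folding to the minor allele — panel variants are rare alternate alleles,
  and the source tables report raw AC/AN.

The two filters commute and are idempotent (property-tested).

### Five-tier classification

The classification engine combines ACMG/AMP evidence codes using the
published combining criteria, encoded as a data-driven table of minimum
counts per strength category (e.g. pathogenic requires 1 very-strong + 1
strong, or 2 strong, ...). Stronger tiers take precedence; conflicting
directions, or no rule firing, yield VUS. The table and the code→strength
map are both overridable, because diagnostic labs routinely deviate from the
published algebra ("largely based on" is the norm); the default is the
published version, verified in tests against an independent brute-force
enumeration of all category-count vectors.

A curated literature lookup (keyed by transcript + cDNA) takes precedence
over evidence combination. It ships pre-populated from the packaged P/LP
fixture, so the fixture reproduction recovers all 20 diagnostic calls
without re-deriving per-variant evidence; 15 of those were literature-known
and 5 were novel calls carried with their reported tier.

### Pathogenicity score

Each of six predictors is normalized to [0,1] (1 = pathogenic) and summed,
giving a 0–6 score. The shipped normalization maps are:

| predictor | raw range | unit score |
|---|---|---|
| SIFT | tolerance prob. 0–1 | piecewise linear: [0, 0.05] → [1, 0.75] (deleterious band), (0.05, 1] → (0.75, 0] |
| PolyPhen-2 | prob. 0–1 | identity |
| MutationTaster | call + prob. | prob. if disease-causing, 1 − prob. if polymorphism |
| AlignGVGD | C0..C65 | class index / 6 |
| PhyloP | ≈ −14..+6 | clamp(raw / 6, 0, 1) |
| Grantham | 0–215 | raw / 215 |

Each map is monotone in the tool's pathogenic direction, bounded, and
overridable via the normalization-map argument. The maps are this package's
own documented defaults: when a source table already prints a pathogenicity
score (as the packaged fixtures do), the printed score is consumed as-is and
never recomputed. A missing predictor contributes 0 and decrements
`n_contributing`; variants assessed only at the splice level carry no score
at all.

### VUS subclasses

The decision tree is: no protein-level score + splice consensus → VUS-splice;
score < 3 → VUS-low; score ≥ 3 + database-present (MAF < 0.1%) →
VUS-semi-high; score ≥ 3 + database-absent → VUS-high. Score exactly 3 is
never low. Two edge policies are deliberate choices, since the source
procedure never exhibits the cases:

* a variant with both a protein score and a splice consensus takes the score
  branch, with the consensus recorded in `splice_flagged`;
* a VUS with score ≥ 3 and MAF between 0.1% and the upstream filter
  threshold cannot normally occur (filtered earlier); defensively it routes
  to semi-high with a warning rather than failing.

### Splice consensus and minigene arithmetic

A splice effect is called when ≥ 3 of the 4 predictors show a relative
WT→variant score change of at least 10% *in the same direction at the same
site*. The 10% default quantifies an unquantified "score difference" — a
pure nonzero-delta rule is numerically fragile — and matches the
conventional significance threshold used with HSF consensus values; it is
overridable. Direction consistency is required because a mixed loss/gain
"consensus" is biologically incoherent. Relative change from a zero WT score
counts as full gain.

The ±3–20 bp follow-up window gates only minigene candidate reporting, not
VUS-splice assignment: mid-exon variants can be (and in the emulated study
were) splice-flagged by consensus, while canonical ±1/2 variants classify
directly and never enter the window. Exonic distances to the nearest
junction require an exon map and are never guessed from cDNA notation.

Minigene constructs are modeled as vector flanks + included exons + retained
intronic bases; `fragment_length` predicts the gel band and
`frameshift_from_skip` applies length mod 3. The packaged worked example
(488 bp wild type, 364 bp after skipping a 124-bp exon, frameshift) is
internally consistent by construction.

### Reclassification

The promotion rule — LP iff segregation supports it or a functional test
indicates it; protein modeling alone never promotes; nothing demotes below
VUS — is *induced* from the 13 published follow-up outcomes: it is the
minimal rule consistent with every row. It is encoded as a data-driven
(field, verdict) table so labs can re-weight evidence. Whether stronger
benign-direction evidence could demote to LB is unobserved in the source
data; the module refuses to demote and documents that refusal. Variants
whose carriers were re-diagnosed with another condition are flagged
`excluded_reclass` and skipped in follow-up counting.

### Reporting conventions

Percentages are truncated, not rounded, to the printed precision: 22/348 →
6.3, 26/348 → 7.4 (7.47 would round to 7.5), 4/13 → 30. The yield delta is
the difference of the truncated yields. The yield denominator defaults to
the 348 analyzable patients, not the 368 enrolled.

## Fixtures

The three packaged TSVs transcribe the study's printed result tables
verbatim (genes, transcripts, cDNA/protein notations, scores, AC/AN strings,
subclasses, follow-up outcomes), with "—" normalized to absent at load and
SHA-256 checksums pinned in the test suite. Row semantics follow the printed
counting: a multi-patient row (e.g. "46, 47") is one variant record, while
the one variant printed twice in the prioritized-VUS table (KIF26B
c.2605G>A, two seemingly unrelated patients) stays two records, matching the
published totals (39 prioritized VUSes, 23 semi-high). The table caption
says 36 patients where the accompanying text says 37; the fixture stores the
IDs verbatim (37 distinct) and the discrepancy is recorded here rather than
resolved. The cohort-wide totals of 105 VUS and 203 LB variants are not
recomputable from printed tables (only the 39 prioritized VUSes are listed)
and are therefore never asserted.

## Synthetic cohorts

`generate_cohort` emulates the study conditions: 368 patients in 92 pools of
4 with a per-pool failure probability of 5/92 (≈ 5 pools drop, leaving
≈ 348 analyzable patients); Poisson(1) variants per analyzable patient
(≈ 330 variants per cohort, matching the 328 post-filter variants of the
emulated cohort); tier mixture 15:5:105:203 and VUS subclass mixture
66:23:12:4. Where the emulated study reports no value, defaults were chosen
once as field-realistic and are stated in `CohortSimConfig`:

* **depth**: negative binomial, mean 50, dispersion 5 — a ≈ 9% tail below 20
  exercises the depth filter;
* **predictor scores**: class-conditional Beta draws on the normalized scale
  (P/LP: Beta(8,2); semi-high/high: Beta(6,2); low: Beta(2,4);
  LB: Beta(1.5,6)), sidestepping the raw-tool scales entirely;
* **gnomAD**: presence probability per class (semi-high 1, high 0, LB 0.9,
  low 0.7, P/LP 0.3) with log-uniform MAF in [10⁻⁶, 9.9·10⁻⁴] for rare
  variants; 15% of raw variants are common polymorphisms (MAF 0.11–5%,
  labelled `truth_common`) so the frequency filter has work to do;
* **splice candidates**: 3 or 4 tools drop by 15–60% (relative), others
  jitter by σ = 2%; HSF CVs behave analogously; 10% of non-candidates carry
  a neutral tool panel to exercise the negative path;
* **follow-up**: families available for 2/39 of prioritized VUSes (always
  supporting LP when available, as observed), protein modeling for 8/35,
  functional tests for all splice candidates and 2/35 of missense VUSes,
  LP verdicts at probability 0.5.

Ground truth travels in `truth_*` columns stripped by `--blind`. Generation
is deterministic per (config, seed) and byte-identical on re-run; every
generated table round-trips through the standard TSV reader, so schema
validity is enforced by construction.

What the simulator does **not** model: linkage between family members,
read-level artifacts (it emits called depths, not reads), gene sequence
content, inter-variant correlation within a patient, and the raw score
scales of the six predictors (scores are generated normalized). Passing
recovery tests therefore demonstrates the pipeline's decision logic, not
robustness to annotation-tool noise on real data.

Test problem sizes: the distributional checks use ≈ 10⁴ variants
(`mean_variants_per_patient = 10`, three seeds) with 3-binomial-SD bounds —
large enough for stable marginals while keeping the whole suite in seconds.
The degenerate-recovery check pushes Beta shapes to the extremes
(Beta(10⁶, 10⁻³) and its mirror) and disables common variants, making every
subclass assignment deterministic; recovery of truth-high variants is then
exactly 100%.

## Known limitations

* The in-house diagnostic decision tree behind the emulated study's routine
  classifications is not public; the engine implements the published
  combining algebra instead, and the fixture reproduction relies on the
  curated lookup rather than per-variant evidence re-derivation.
* The per-predictor normalization that produced the printed fractional
  scores (3.1, 4.1, 5.1) is not public either; the shipped maps are sane,
  monotone and bounded, but will not reproduce those third-party values from
  raw tool outputs.
* How 17 in-silico splice candidates were manually narrowed to 4 VUS-splice
  is described only qualitatively in the source; `hsf_verify` encodes the
  stated verification step, but the full manual triage is not reproducible.
* VCF ingestion maps flat INFO keys onto the schema; nested annotation
  formats (VEP CSQ strings) must be flattened upstream.
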