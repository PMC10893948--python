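# Methods

This note documents the models, defaults and numerical choices behind
`radpanel`, and what the synthetic-panel tests do and do not establish
about real data.

## Dosage model

Gene-level read counts are normalized to RPKM (reads per kb of gene model
per million mapped reads); the per-gene copy estimate is
`k = 2 * rpkm / m_g`, where `m_g` is the median RPKM of the untreated
controls (at least 3 required; 16 is the intended design).  Genes with
`m_g < 0.5` RPKM are masked: below that, the ratio's denominator is too
unstable for dosage work, and in transcriptome mode it removes genes that
are simply not expressed in leaf tissue.

Because RPKM shares a per-sample total, a plant carrying several large
duplications has every ratio deflated (and a heavily deleted plant
inflated).  `estimate_copies` therefore rescales each sample so its
genome-wide median `k` is exactly 2 (`recenter=True`, the default).  This
is valid while most of the genome is at baseline copy number — true for
any real mutagenized plant — and breaks only in the absurd regime where
more than half the gene space is aberrant.

Tile colours are `C = clamp(k_A/4)`, `M = clamp(k_C/4)`, Y = K = 0.  The
channel formulas are fixed by the lighter-deletion / darker-duplication
contract and by saturating at two extra copies; no higher amplification
class is distinguished.  For rendering, CMYK is converted as
`R = 1 − C, G = 1 − M, B = 1`.

## CNV caller

Per subgenome and chromosome, `k` is smoothed with a running median
(window `w`, truncated at chromosome ends; masked genes are skipped).
Maximal runs with smoothed `k < 1.5` (deletion side) or `> 2.5`
(duplication side) seed candidate events; 1.5 and 2.5 are midway between
adjacent integer copy states, the maximal-margin choice under symmetric
noise.  Candidate handling then applies, in order:

1. **Gap bridging.**  Same-state runs merge across gaps shorter than
   `w/2` genes, or across longer gaps whose *raw* mean `k` stays on the
   event side of 2 by more than 0.25 — a sub-threshold sag inside one
   lesion rather than two lesions.  The gap is judged on raw values
   because a window-wide median straddling a short baseline gap between
   two genuine lesions is dragged to the lesion level.
2. **Length filter.**  Runs shorter than `min_run = 10` usable genes are
   dropped.  This is the operational meaning of a "visible" event in the
   dose-response tables.
3. **Boundary extension.**  A confirmed run grows outward while the
   smoothed value stays beyond the midpoint between baseline and the
   event state (1.75 / 2.25), by at most `w/2` genes per side — the
   amount by which a `w`-gene median erodes a lesion's shoulders.  The
   cap stops boundaries wandering along autocorrelated baseline noise;
   extension never creates calls.
4. **Amplitude guard.**  A run must depart from baseline by at least 0.5
   copies in its raw mean, with a one-sample *t* statistic of at least 4.
   A running median can drift past a threshold for roughly a window
   length on autocorrelated noise alone; the amplitude test is what
   separates such excursions from genuine half-copy shifts.  On balanced
   simulated panels this holds the false-call rate below 0.01
   events/plant while costing no measurable sensitivity for ≥ 10-gene
   real events.
5. **Copy state and splitting.**  Post-event copies come from the mean
   smoothed `k` via the cut points 0.5/1.5/2.5/3.5; copies 0/4 are
   homozygous, 1/3 heterozygous.  Deletion runs are split where the
   integer copy level changes and both sides span `min_run` genes with
   means differing by ≥ 0.75 (a homozygous deletion abutting a
   heterozygous one); duplication runs are never split, because at 1.5×
   depth the 3-versus-4-copy distinction is too noisy for reliable
   sub-segmentation.
6. **Whole-chromosome reclassification.**  Runs covering ≥ 95% of a
   chromosome's genes become chromosome loss/gain with the full
   chromosome as their interval.

Window defaults: `w = 15` for genome re-sequencing, `w = 31` for
transcriptome data (`CallerParams.for_mode`), reflecting the roughly
twofold-noisier per-gene ratios of expression data.

**Homoeologous exchanges** are reassembled from their dosage signature: a
duplication on one subgenome and a deletion on the homoeologous interval
of the other, with reciprocal overlap ≥ 0.7 in homoeologue-pair space,
merge into one exchange call on the gaining subgenome (direction
recorded, e.g. `A->C` when A-genome sequence replaced the C segment).

**Single-gene scan.**  Per (gene, sample), `r = k / median across
samples`; candidates at `r ≥ 1.75` (duplication) or `≤ 0.25` (homozygous
deletion) outside called segments, ranked by |log2 r|.  This reproduces a
manual scan of population-normalized depth spreadsheets; at 12×-like
noise a handful of single-gene false candidates per ~10⁵ gene×sample
cells is expected, which is why candidates are ranked for validation
rather than asserted.

**Dose-response tables** count events per plant per class (exchanges
excluded — they are pre-existing seed-lot variation, not radiation
lesions), rounded half-up to 2 decimals; the summary column is the
unweighted mean of the four visible deletion/duplication rates, rounded
the same way.

**Saturation estimator.**  `N = ceil(target / (rate × fraction))` lines
gives an expected `target` independent deletions of any fixed genome
point, with `rate` deletions per plant each covering `fraction` of the
genome.  With the panel-wide deletion rate (~2.5/plant summing both
subgenomes) and a typical visible deletion spanning ~0.2% of the genome
(~1.7 Mb of ~850 Mb), five-fold deletion saturation needs ~10³ lines.
The estimator exposes both inputs rather than hard-coding either.

## Variant filter chain

Order: per-sample quality filter → control subtraction → occurrence
filter → region restriction and consequence classification.  Choices the
upstream tools leave ambiguous:

* QUAL is strict (`> 20`); the SnpGap rule removes SNVs within 3 bp of a
  *retained* InDel but never removes InDels.
* Control subtraction is position-level (any allele at a control
  position), matching the motivation: a position that varies in
  untreated material is pre-existing variation or a systematic artifact.
* "Occurrence greater than 8" is read as *removal* of variants present
  in more than 8 lines: independent radiation events should be
  line-specific, so recurrence indicates artifacts.  Both the threshold
  and the direction are arguments.
* Multi-allelic records are split before filtering.  Every record keeps
  an append-only `filter_history`, so survivors ∪ rejects always equals
  the input.

Validation tiers by variant-allele read depth: `standard` (VAD > 2),
`low` (VAD = 2), `reject` (VAD < 2); tier validation percentages are
reported in both integer and one-decimal renderings since published
figures use both.

The consequence classifier translates codons with the standard nuclear
code, is strand-aware, and reports synonymous / missense / stop_gained /
stop_lost for SNVs; indels are in-frame (with the amino-acid count) when
the length change is divisible by 3, else frameshift; intronic or
flanking positions within 2 nt of a CDS boundary are splice_site.  It is
a deliberate simplification of a full effect-prediction suite: one
transcript per gene, no UTR or regulatory classes.

## IHP genotyping

The A-base signal proportion `p = I_A / (I_A + I_C)` is scale-invariant
in amplification efficiency.  The default hypothesis set
{0A:2C, 1A:2C, 2A:2C, 4A:2C, 2A:0C} has expected proportions
{0, 1/3, 1/2, 2/3, 1}, spaced ≥ 1/6 so the 0.08 no-call margin keeps the
classes disjoint.  The heterozygous-duplication state 3A:2C (p = 0.6,
only 0.067 from 4A:2C) and 2A:1C (p = 2/3, indistinguishable from 4A:2C
by proportion alone) are not defaults; pass `EXTENDED_CLASSES` or an
explicit set when a line's segregating states warrant them and the extra
ambiguity is acceptable.  Accuracy statements are over made calls; a
no-call is a refusal, not an error (≈ 0.8% refusals at σ = 0.03).
Consensus across the markers of one amplicon is a strict majority vote;
ties no-call with the per-marker detail retained.

## Trait model

Group comparisons use Welch's unequal-variance *t* with
Benjamini–Hochberg adjustment across the comparisons of one analysis;
the published-style labels are `**` (adjusted p < 0.005) and `****`
(< 0.00005), configurable.  Identical constant groups short-circuit to
t = 0, p = 1 rather than 0/0.  Expected directions: FAE1 copy loss →
erucic ↓, oleic ↑; FAE1 gain → erucic ↑; FAD2.A5 loss → linoleic ↓,
oleic ↑, erucic ↑.

## Synthetic panel generator

The generator's defaults are the study conditions of the calibration
experiment: 10 A + 9 C chromosomes; gamma doses 750–2000 Gy with 8 M1
families × 2 sibs, fast-neutron doses 40–100 Gy with 8 × 1; 16 untreated
controls.  Rate coefficients are per-Gy Poisson rates equal to the
2000 Gy per-plant class rates divided by 2000 — lesion counts are linear
through the origin in dose, the simplest form consistent with a monotone
dose response.

A lesion heterozygous in the selfed M1 is visible in 3/4 of offspring,
so family-level class counts are drawn Poisson(rate × dose × 4/3) and
each lesion segregates 1:2:1 (hom-absent : het : hom-present) per
genotyped sib; observed per-plant rates then equal rate × dose exactly
when the reciprocal pathway is off.  With probability `recip_prob`
(default 0.3) a deletion is instead inherited reciprocally: one sib
carries the heterozygous deletion, another the matching heterozygous
duplication.  Segment lengths are log-uniform between 5 genes and the
chromosome length (lesion size is dose-independent); lesions of one
family never overlap on a chromosome, and whole-chromosome events claim
their chromosome before segmental draws, so every simulated event's copy
state is unambiguous — without this, overlapping truth makes caller
evaluation ill-defined.  Homoeologous exchanges occur in every line
(controls included) with probability 0.1, hom or het, direction random.

Read counts are negative binomial with mean
`mean_depth × (len/1 kb) × copies/2`.  Genome mode: `mean_depth = 80`
reads/kb (≈ 12× coverage with 150 b reads on ~2 kb genes) and dispersion
60 — a ~160-read gene count has 8% Poisson CV and library/mappability
effects add ~10%, so extra-Poisson CV ≈ 13%.  Transcriptome mode:
`mean_depth = 60`, dispersion 25 (biological CV ≈ 0.2 between
near-isogenic sibling plants under controlled conditions, the standard
magnitude for genetically identical biological replicates) and a
per-gene lognormal expression factor with CV 0.4 shared across samples.
Things the generator deliberately does not model: GC/mappability bias
structured along chromosomes, mapping ambiguity between homoeologues,
batch effects, partial aneuploidy mosaicism, and read-level data.
Passing tests therefore demonstrate the pipeline's correctness and
statistical behaviour under its stated assumptions, not robustness to
alignment artifacts.

Simulated variants comprise true line-specific SNVs/InDels, false calls
whose validation probability is stratified by variant-allele read depth
(defaults 0.38 for VAD > 2 and 0.035 for VAD = 2), systematic artifacts
shared across many lines and controls, pre-existing variation present in
the control master set, and low-QUAL noise records.  Phenotypes are
additive: erucic % = 10 + 9 × (functional FAE1 copies) + 2 × (FAD2.A5
copies lost); linoleic % = 15 − 3.5 × (FAD2.A5 copies lost); oleic % =
15 + 2 × (FAD2.A5 copies lost) + 1.5 × (FAE1 copies lost); Gaussian
residual SD 1.0.  These anchor a wild type at ≈ 46/15/15 and a FAD2.A5
null at ≈ 50/8/19 (erucic/linoleic/oleic).

Determinism: every stage draws from an independent stream spawned from
`(config.seed, stage)`, so identical configuration gives byte-identical
outputs and regenerating one stage does not perturb another.

## Evaluation conventions and problem sizes

Caller benchmarks use 200 gene pairs per A chromosome (4 000 pairs, a
five-fold scale-down of the ~20 k-pair gene space that preserves
per-chromosome gene counts in the hundreds), 200 treated plants at
2000 Gy for recovery, 100 balanced plants for false positives, and
10 000 plants for rate calibration.  A truth lesion counts as recovered
when a same-direction call overlaps it with interval Jaccard ≥ 0.5
(sensitivity is restricted to lesions ≥ 30 genes, precision to calls
≥ 30 genes; near-complete segmental calls and whole-chromosome truth
match either way).  Genome-versus-transcriptome agreement uses a
coverage criterion instead — a lesion is detected in a mode when ≥ 75%
of its interval is covered by same-direction calls — because the claim
under test is equal *detection*, and boundary wobble between windows of
15 and 31 genes should not count as disagreement.  Equal detection is
asserted at ≥ 99% agreement over ≥ 30-gene lesions: at the configured
transcriptome noise an occasional heterozygous duplication near 30 genes
sits at the detection margin of either mode, so exact set identity is a
property of the noise draw rather than of the method; measured agreement
is typically 100%.

## Known limitations

* Gene-order coordinates throughout; breakpoints are not refined to base
  pairs, and bp positions appear only in the variant module.
* The exchange detector pairs one duplication with one deletion; complex
  nested exchanges are not modelled.
* The consequence classifier handles one CDS model per gene and the
  standard code only.
* The saturation estimator is a fixed-point expectation; it ignores
  length heterogeneity beyond the mean fraction and any clustering of
  breakpoints.
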