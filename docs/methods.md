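# Methods

This note records the statistical model behind each estimator and
simulator, the default parameters, and the numerical and design choices a
user should know before trusting the outputs.

## 1. Informative-SNP mixture estimation

### Model

A recipient cell population carries endogenous mtDNA (the *recipient
haplotype*) and, after augmentation, a fraction *f* of exogenous mtDNA (the
*donor haplotype*). At any site where the two haplotypes differ — an
*informative SNP* — the expected donor-allele frequency among sequencing
reads is

```
E[freq] = f·(1 − e) + (1 − f)·e/3
```

where *e* is the per-base substitution error rate (errors are assumed
uniform over the three alternative bases). The estimator ignores the error
terms and reports

```
percent exogenous = 100 × mean(donor-allele frequency over passing SNPs)
SEM               = 100 × sd(per-SNP frequencies, ddof=1) / √n
```

The unweighted mean over sites (rather than a depth-weighted pool) keeps
one aberrant high-depth site from dominating and makes the SEM a plain
between-site statistic. Consequence of ignoring the error terms: a
**floor of ≈ 100·e/3 percentage points** (0.033 pp at the default
e = 0.001) on pure-recipient samples, and a matching ceiling below 100% on
pure-donor samples. This bias is documented rather than corrected because
the true error rate of real data is unknown and the floor is far below the
biologically relevant fractions.

### Pileup

Alignments (SAM/BAM) are streamed once; records that are unmapped,
secondary or flagged duplicates are skipped (supplementary records are
kept — split reads across the circular origin or a deletion junction carry
real bases). Filters: mapping quality ≥ 20, base quality ≥ 20, per-site
depth ≥ 100 (all configurable). One base per *fragment* per site is
counted: if both mates of a pair (or a primary and its supplementary
segment) cover a site, the higher-base-quality call wins, so overlapping
mates are not double-counted. CIGAR walking supports M/=/X, I, S (query
only), D, N (reference only); the reference name/length in the header must
match the supplied haplotype.

### Site filters

SNPs are flagged (and excluded by default) when they fall in a
homopolymer run of ≥ 5 identical bases in either haplotype, inside a
declared deletion interval (allele frequency there conflates mixture with
heteroplasmy), or inside user-supplied excluded regions (e.g. rCRS
hypervariable segments HVS-I/II/III, provided as a constant). Flagged
sites can be re-included explicitly.

## 2. Read simulator

`simulate_reads` generates paired-end reads (2 × 150 bp by default) from a
circular genome of default length 16,569 bp, at a target coverage (default
2500×), with i.i.d. substitution errors (default 0.001/base) and fixed Q30
base qualities. The number of pairs is `round(coverage × L / (2R))`
(138,075 at defaults). Fragments are length `2R + insert_gap` (default
350 bp) and positioned uniformly on the circle in `rca_uniform` mode, or
uniformly within two (by default overlapping) amplicon intervals in
`pcr_two_amplicon` mode with a configurable depth ratio between amplicons.
Output is a truth-coordinate SAM (no aligner involved; reads spanning the
circular origin or a deletion junction are emitted as primary +
supplementary records with soft clips, or with a `D` CIGAR op), optional
FASTQ, and a truth TSV with per-read molecule-of-origin labels.

### Molecule classes and mass-weighted sampling

Each fragment originates from one of three molecule classes: donor
(mixture fraction *f*), recipient full-length, or recipient deleted (when
the recipient carries a deletion at heteroplasmy *h*). Class probabilities
are **proportional to molecule abundance × molecule length**
(mass-weighted):

```
P(donor)              ∝ f · L
P(recipient full)     ∝ (1 − f)(1 − h) · L
P(recipient deleted)  ∝ (1 − f)·h · (L − deletion length)
```

Rationale: *f* and *h* are defined as *molecule-count* fractions, but
shotgun fragmentation yields fragments per molecule in proportion to
molecule length. Sampling classes by molecule count alone would
over-represent the shorter deleted molecule per unit length and bias the
read-level donor-allele frequency downward (at f = 0.054, h = 0.835 with
the 4,978 bp deletion, the recovered mean would be ≈ 4.2% instead of
5.4%). With no deletion the weights reduce to Bernoulli(f) exactly. A
side effect: with a deletion present, depth at sites outside the deletion
is higher than nominal coverage (coverage is defined as total sequenced
bases / L).

## 3. Digital PCR

A chip partitions template into `n_valid` partitions (default 20,000);
with mean occupancy λ, the positive fraction is `p = 1 − exp(−λ)`, so
`λ = −ln(1 − p)`, `copies/chip = λ·n_valid`, `copies/ng = copies/chip /
ng_loaded`. A fully positive chip raises a saturation error (λ is
unbounded). The 95% CI is a Wilson score interval on *p* transformed
through the same relations — a pragmatic choice; vendor interval
constructions are typically unpublished.

Deletion heteroplasmy pairs a *full-length* assay (target inside the
deletion, detecting only non-deleted molecules) with a *total* assay
(target outside): `heteroplasmy = 100 × (1 − FL/total)` on ng-normalised
copies. Sampling noise can push FL slightly above total near h = 0; the
result is clamped to 0 with a warning and a `clamped` flag rather than
erroring. Dual-probe SNP fractions quantify each dye channel
independently (double positives count in both channels — an
independent-target approximation, since co-occupancy statistics are
instrument-specific).

The chip simulator draws the molecule count `M ~ Poisson(copies/ng × ng)`
and assigns each molecule to a uniformly random partition; partition
volume is not modelled, so copy numbers are meaningful per chip and per ng
only.

## 4. Fluorescence-ratio mitochondrial content

Per cell, the donor channel reads `gain × (exogenous mito content)` and
the total-mitochondria stain reads total content. The channel gain is the
median donor/total ratio over *calibration cells* whose mitochondria are
entirely donor-derived (≥ 10 required). Each recipient cell's exogenous
fraction is `(donor / gain) / total`; the estimate is 100 × the median over
recipient cells (single-cell intensities are heavy-tailed, approximately
lognormal, so medians are used throughout), with a percentile bootstrap
95% CI (500 resamples, seeded). Recipient cells are identified as
non-calibration, lineage-marker-negative rows of the panel.

The simulator draws per-cell total content lognormal (median 1000 a.u.,
CV 0.6) and corrupts both channels with independent unit-median lognormal
noise (`sigma = sqrt(ln(1 + cv²))`), so the per-cell ratio has median equal
to the true fraction and the estimator is median-unbiased by
construction; residual bias from the noisy gain estimate is well under the
1 pp test tolerance.

## 5. Assay arithmetic

- Complex-IV respiration: `OCR(TMPD/ascorbate) − OCR(azide)`; negative
  results are returned with a warning (instrument drift/failed injection),
  not clamped.
- Kinetic background subtraction: pointwise signal − no-substrate blank;
  negative points warn but are kept so slope fits see raw behaviour.
- COX-1 fold change: `(treated COX-1 / treated Janus) / (control COX-1 /
  control Janus)` — cell-number-normalised.

## 6. Reproducibility

Every stochastic stage takes an explicit seed. Pipeline runs derive
per-stage seeds as `sha256(f"{global_seed}:{stage}:{replicate}")` truncated
to 31 bits, giving independent streams without hidden global state; reruns
of the same config are byte-identical (floats in reports are serialised at
4 significant digits). Benchmark problem sizes (16,569 bp genome, 30
SNPs, 2500×, 20,000 partitions, 500-cell panels, 20 replicate seeds) were
chosen so each recovery completes in minutes on one CPU while Monte-Carlo
error stays well inside the stated tolerances.

## Limitations

- Substitution errors only: no indel errors, no quality-score variation,
  no PCR duplicates, no strand bias, no alignment artefacts (reads are
  emitted at truth coordinates, so mapping error is out of model).
- The error floor ≈ e/3 on mixture estimates is reported, not corrected.
- dPCR partitions are volume-less and molecules independent; no partition
  volume CV or rain (intermediate-amplitude partitions).
- The fluorescence model assumes the donor marker scales linearly with
  exogenous content and a single global gain; photobleaching, segmentation
  error and autofluorescence are not modelled.
- Heteroplasmy enters the read simulator only through molecule-class
  abundance; replication advantage of shorter molecules over time is not
  modelled.
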