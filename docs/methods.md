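# Methods

This note documents the models, conventions, and design choices behind
allovax, in the spirit of the methods documentation of quantification and
meta-analysis toolkits. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` compute.

## HLA nomenclature and reference augmentation

HLA alleles are parsed into a locus (one of HLA-A, -B, -C, -DRA, -DRB1,
-DRB3, -DRB4, -DRB5, -DQA1, -DQB1, -DPA1, -DPB1) and 1–4 colon-separated
numeric fields with leading zeros preserved. The first three fields define
the coding sequence (CDS level); the fourth distinguishes non-coding
variants. Parsing strips the optional `HLA-` prefix and any internal
whitespace — printed tables often carry typographic spaces inside allele
names — and the gene is stored canonically *with* the prefix. Matching at
resolution *n* is strict by default: both alleles must carry at least *n*
fields; a two-field typing therefore never "matches" at the CDS level, and
group matches are reported as what they are.

The augmented transcriptome is `(reference − removals) ∪ insertions`:
reference HLA transcripts the line does not carry are removed (the removal
list is an explicit input file rather than being inferred by gene name, so
a curated list can be swapped for a synthetic one), and the line's typed
allele CDS sequences are inserted under their canonical allele names, which
makes downstream abundance tables self-describing. Per-subject typings
distinguish a locus typed as absent (an empty allele list, as for secondary
DRB loci present only on some haplotypes) from an untyped locus (absent
from the mapping entirely).

## Quantification model

**Index.** Every length-*k* substring of every transcript is indexed under
its canonical form (the lexicographically smaller of the 2-bit-encoded
k-mer and its reverse complement), mapping to the set of transcripts
containing it. Defaults: *k* = 21, read length 150. *k* = 21 rather than a
longer word suits desk-scale synthetic transcriptomes where allele pairs
diverge every ~12 bases on average; it is configurable. The effective
length is `max(1, L − read_length + 1)` — transcripts shorter than the
read length are floored at 1, not dropped.

**Pseudoalignment.** A read's compatibility set is the intersection of the
transcript sets of all its k-mers *found in the index*; k-mers absent from
the index are skipped rather than vetoing the read, which tolerates
substitution-type sequencing errors without error-aware alignment. Reads
with no indexed k-mer, or an empty intersection, are unassigned. Counts
are keyed by the sorted compatibility set (equivalence classes).

**EM.** From uniform initialization, estimated counts update as

    α_t ← Σ_ec c_ec · (α_t/ℓ_t) / Σ_{t'∈ec} (α_{t'}/ℓ_{t'})

until the maximum relative change drops below 1e-8 or 1000 iterations
(non-convergence is flagged and logged, never silently accepted). This is
the EM for the mixture likelihood `Σ_ec c_ec log Σ_{t∈ec} θ_t/ℓ_t` in the
read fractions θ; the per-iteration log-likelihood is recorded and checked
non-decreasing in the tests, and the estimator is validated against a
dense-grid likelihood search on small instances. Total estimated counts
equal assigned reads after every iteration. Degenerate fully-shared
classes resolve to equal abundances by symmetry of the update.

**TPM and calls.** `tpm_t = 1e6 · (α_t/ℓ_t) / Σ_u (α_u/ℓ_u)`; an all-zero
table yields all-zero TPM. A transcript is *expressed* iff TPM strictly
exceeds the threshold. The threshold defaults to 1.0 but is configurable,
since "above approximately 1" is a judgment call; the strict `>` makes the
boundary decision explicit and testable. Only plain TPM is computed — no
regression-based cross-sample normalization, no bias correction, no
bootstrap variance. This is a deliberate simplification: the analyses here
interpret TPM values directly.

**Single-end by default.** Quantification and simulation use single-end
150-base reads even though real libraries are often paired-end: pairing
adds no information to a k-mer compatibility model without fragment-length
modelling, and read length is configurable.

**UTR experiment.** The same read set is quantified against two indexes
that differ only in whether allele entries carry untranslated regions.
When reads derive from full transcripts but only the CDS is indexed, reads
overlapping the CDS flanks still pseudoalign while the allele's effective
length stays short, inflating its rate, and pure-UTR reads go unassigned;
including the UTRs therefore *lowers* the allele's TPM while leaving it
well above the expression threshold when the allele is truly expressed.
The experiment reports per-allele TPM under both indexes and their ratio.

## Match classification

A locus matches at **allele** level when a patient allele and a line
allele agree over the first three fields *and* the line allele passes the
expression gate — expressed in at least one of the vehicle / IFN-γ
conditions, since inoculation sites are expected to provide an
inflammatory milieu. Failing that, **group** matches are tried at two
fields, then one, reporting the finest resolution at which any pair
matches; the gate applies at group resolution too (configurable, since one
could argue a group match concerns the locus rather than a specific
allele). Group-level pairs are also recorded at loci that already have an
allele-level match through a different allele pair, so a locus can carry
both an allele match and an additional group match. Sequence matches to
unexpressed line alleles are collected in `expression_gated_out`.
Homozygous alleles count once. Loci untyped on either side yield level
`none` flagged `untyped`, not an error. Class rollups count loci with
allele-level matches: HLA-A/B/C as Class I; the DR/DQ/DP loci as Class II.

## Grade signature and RMG

Each study is a genes × samples matrix of log2 intensities with per-sample
grades in {1, 2, 3} and at least two samples per group. The per-study
contrast is a Welch two-sample t-test per gene, grade 3 vs the pooled
grade-1∪2 reference, with Benjamini–Hochberg correction within the study
(matching a per-study query design); a gene passes iff
|log2 FC| ≥ log2(2) and q ≤ 0.01, both inclusive. The test statistic
itself is a choice — the upstream analysis platform does not name one —
and is the standard two-group microarray contrast; it is configurable.

The consensus requires a gene to pass in ≥5 studies *with the same
direction* (direction consistency is imposed here and configurable); its
weight is the mean log2 fold change over the qualifying studies. The RMG
of sample *s* is computed from the cohort matrix as

    raw_s = Σ_g w_g · z_{g,s},   rmg_s = 100 · (rank(raw_s) − 0.5) / n

with per-gene z-scores across samples (zero-variance genes contribute 0)
and average ranks for ties. The 0–100 scaling and rank-percentile form are
this package's operational definition: the published description gives the
ingredients (expression levels weighted by meta-analysis fold changes, on
a 0–100-looking scale) but not a formula, so RMG values are comparable
within a cohort, not across publications. Higher RMG = more grade-3-like
(less differentiated); this direction convention is stated here because
prose descriptions of "relative differentiation" are ambiguous. Signature
genes absent from a cohort matrix are dropped with a warning; a cohort
with no usable signature genes is an error.

## Clinical summaries

Cohort medians over an even number of subjects are the mean of the central
pair and are additionally reported rounded half-up to integer days — the
convention needed to reproduce published integer summaries (94.5 → 95,
143.5 → 144); the raw medians are always emitted alongside. Survival
threshold comparisons are strict (`>`), matching "more than N months"
phrasing. Off-protocol retreatment series are stored on the subject record
but never enter cohort summaries. The adverse-event total counts each
term-patient pair once plus explicitly recorded repeat observations; grade
ranges are carried as free text with no grading arithmetic. DTH summaries
take the largest diameter over inoculation sites per subject × visit,
separately for erythema and induration. Serology responses are percent
change of median fluorescence intensity versus a same-subject,
same-dilution baseline. qPCR relative expression is 2^−ΔΔCt against a
reference gene and calibrator sample, also reported as percent of
calibrator.

## Synthetic data

The generators produce every input the pipeline consumes, deterministically
per seed:

- **Allele pairs**: a uniform-composition random sequence plus a copy with
  `round((1 − identity) · L)` substitutions at uniformly drawn positions,
  targeting the ~91–93% pairwise identity of confusable HLA allele pairs
  (default 0.92). No codon structure is claimed.
- **Transcriptomes**: mutually dissimilar random background transcripts
  (1500 b default) plus allele pairs (1100 b) and, per pair, a decoy
  "reference HLA" transcript at ~90% identity placed in the reference and
  listed for removal — emulating generic reference alleles the line does
  not carry.
- **Reads**: transcripts drawn with probability ∝ TPM × effective length,
  uniform start positions, per-base substitution errors (default 0.005, a
  typical short-read scale; no indels — k-mer skipping handles
  substitutions and indel realism is out of scope). Transcripts shorter
  than the read length contribute whole-transcript reads. A truth table
  records planted TPM and realized counts.
- **Grade studies**: per study, independent per-gene baselines ~N(8, 1),
  Gaussian noise (σ = 0.5 default), and a signed planted log2 fold change
  (2.0 default) added to grade-3 samples of the planted genes, which
  alternate up/down. Defaults are 7 studies, 2000 genes, 40 samples per
  grade group, 30 planted genes.
- **Cohort typings**: per-subject, per-locus requested match levels
  (allele / group / none) are realized against a line typing, optionally
  respecting its expression gate; unsatisfiable requests (e.g. a match at
  a locus the line lacks) raise an error.

What the generators do *not* emulate bounds what passing tests show about
real data: no empirical error or GC profiles, no real HLA sequences or
linkage structure, no cross-study normalization artifacts, no batch
effects. Recovery results demonstrate the estimators are correct under
their stated models, not that real libraries meet those models.

## Problem sizes and numerical choices

The simulation-based checks run at desk scale, chosen so the full suite
and the acceptance script complete in minutes on one CPU while leaving the
conclusions unchanged: 200k reads for parameter recovery (two 92%-identity
allele pairs, recovery within ±15% for transcripts with true TPM ≥ 100;
the real study sequenced ~30M reads/sample, which this package does not
attempt to reproduce numerically), 100k reads for the UTR comparison,
full-size (2000-gene, 40+40-sample) study matrices for the meta-analysis
with 50 null replicates. EM tolerance 1e-8 (relative), max 1000
iterations; grid oracles use step 5e-4 on the simplex. Ties in RMG ranks
use average ranks; truncating an allele to its own resolution returns the
identical object; truncation never pads.

## Known limitations

- HLA typing itself is out of scope: typings are inputs. Deducing alleles
  of untyped loci from reads (as done informally for DRA/DQA1/DPA1 in the
  motivating study) is not reconstructed.
- The quantifier has no fragment-length model, no bias correction, and no
  uncertainty quantification; expression calls near the 1-TPM boundary at
  low depth are sampling-noise limited.
- The consensus signature and RMG reproduce a *procedure*, not a published
  gene list: the source microarray corpus is proprietary, so the published
  55-gene list and specific RMG values are not recoverable from this
  package, and RMG is defined only up to within-cohort ranking.
- Survival handling is purely descriptive (threshold counts); no
  Kaplan–Meier or Cox modelling, no RECIST logic.
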