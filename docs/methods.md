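# Methods

## Scope and model

The package analyses a CLIP experiment of the classical Sanger-cloned
kind: a few hundred clone sequences, each expected to read
`adapter5 + insert + adapter3` on one strand, where the insert is an RNA
fragment protected by the immunoprecipitated protein. The analysis
quantities are (i) the triage of distinct tags into contaminant /
unmapped-or-multimapped / uniquely mapped, (ii) where uniquely mapped tags
fall relative to gene models, (iii) the geometry of tag-containing introns,
(iv) k-mer and motif enrichment over the tag set, and (v) fold-change
categorization of an accompanying two-condition expression table. No
statistical model is fitted; the outputs are deterministic functions of the
inputs plus two classical tests (Welch's t, Kolmogorov–Smirnov in the test
suite).

## Conventions that matter

- **Coordinates** are 0-based half-open everywhere internally and in BED
  output; GTF output is 1-based inclusive; human-readable reports may be
  1-based.
- **Alphabet**: sequences are stored as DNA (T); every motif/k-mer report
  uses the RNA view (U), conversion being presentation-only.
- **Distinct tags**: "tags" are distinct insert sequences. k-mer counting
  is over distinct tags, unweighted by clone support; clone counts are
  retained for reporting only.
- **Intron distances** use the exclusive-gap convention: the number of
  intronic nucleotides strictly between the splice junction and the tag's
  proximal end. This makes
  `dist_upstream + tag_length + dist_downstream == intron_length` an exact
  invariant, asserted on construction of every context. "Upstream" is the
  donor side in transcription direction, so strand flip swaps the two
  distances exactly. The ±1 ambiguity relative to an inclusive convention
  is immaterial at the 500-nt threshold used for proximity fractions.
- **Feature classification** is majority per-base overlap, with ties broken
  toward `cds`, then `intron`, then `utr5`, then `utr3`. Overlapping genes:
  known beats unknown, then larger overlap, then lexicographic gene id.
  "Unknown gene" is an input flag on the model, never an inference.
- **Adapter matching** is exact by default (`max_mismatches=0`), with an
  optional Hamming tolerance; the leftmost 5'-adapter / rightmost
  3'-adapter pair is excised, and an insert still containing an adapter
  copy is rejected as ambiguous rather than re-trimmed. Clone reverse
  complements are searched by default (plasmid clones are read from either
  end); this is a flag.
- **k-mer windows** overlap at step 1 (so `UGUG` contains two `UG`s);
  N-containing windows are dropped from counts and totals; tags shorter
  than k contribute no windows. The chance line is
  `total_windows / 4^k` — the incidence if all k-mers of that length were
  equally represented. A composition-adjusted expectation (product of
  observed mononucleotide frequencies) is available as an option; see
  "Nulls for motif controls" below.
- **Fold change** is the linear absolute ratio `max(a/b, b/a)`; the
  ≥1.5-fold gate is inclusive, the 2-fold "strong" subset strictly
  exclusive (`> 2`). The detection floor defaults to exactly 0 (a gene is
  "exclusive" to one condition only if the other side is 0), with a
  configurable epsilon for FPKM noise.
- **Geometry summaries** report mean, SEM (sample sd with n−1 over √n),
  median (mean of the central pair for even n), min, max. A single-context
  summary reports SEM 0 with an explicit undefined flag.
- **Welch test**: t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite
  degrees of freedom, delegated to `scipy.stats.ttest_ind(equal_var=False)`;
  the caller must declare the one-tailed direction (default: first group
  greater). Two identical degenerate groups return t=0, p=0.5; degenerate
  groups with different means are an error rather than an infinite
  statistic.

## The synthetic generator

The generator emulates the *structure* of the experiment, not its
biochemistry. Defaults define the standard study conditions and are not
tuned per analysis:

| knob | default | rationale |
|---|---|---|
| genome | 1 chromosome × 2 Mb, uniform composition | smallest scale at which 60 multi-exon genes with heavy-tailed introns fit comfortably; full pipeline runs in seconds |
| genes | 60; 3–6 exons of 80–300 nt; 150 nt 5'UTR, 300 nt 3'UTR; one transcript per gene | minimal structure exercising every feature class |
| intron lengths | log-normal, median 3 kb, 15 % of mass above 10 kb (σ ≈ 1.16 from those two constraints) | median matches typical vertebrate introns of a few kb; the stated tail fraction produces the "large intron" regime the analyses probe |
| unknown-gene fraction | 0.10 | a visible minority, as in poorly annotated genomes |
| binding sites | 40 copies of `UGUGUG`, uniform over eligible intronic positions, written in the gene's sense orientation, non-overlapping | UG-repeat is the canonical CELF-class element; no positional claim is modelled |
| clones | 500; insert length uniform 20–60 nt; 50 % of genomic clones site-derived; 10 % contaminant; 5 % malformed (missing 5' adapter / missing 3' adapter / adapters swapped, equiprobable); whole-clone reverse-complement emission with p = 0.5 | Sanger-scale library with the failure modes the extractor must name |
| adapters | two fixed 20-mers, neither a substring (nor the reverse complement) of the other | the original vector adapters are unstated; they are free parameters here |
| contaminant reference | one 1.5 kb random "rRNA-like" sequence, slightly GC-shifted, independent of the genome | enough to exercise exact-substring screening |

The expression-table generator plants per-gene categories (shared up /
shared down / control-only / knockdown-only / unchanged) with fold changes
drawn at or above the 1.5 gate (threshold × 2^Exponential), exact zeros on
the silent side of exclusive genes, and significance flags on every
non-unchanged gene; `de_truth_summary` converts the planted categories into
the oracle summary.

What the generator does **not** emulate: sequencing error, quality scores,
alternative isoforms (tests construct the two-isoform case explicitly),
spliced tags, mismatch alignment, real rRNA databases, or the
mapping-failure modes of a real genome (repeats, paralogy). Passing
recovery tests therefore demonstrate correctness of the bookkeeping and
arithmetic under clean data, not robustness to real-library noise — the
import paths (BED6 alignments, external DE tables, intron-context tables)
exist precisely so real-data equivalents can be substituted.

## Numerical and degenerate-input choices

- Gene placement divides each chromosome into equal slots and rejects
  intron draws that would overflow a slot (up to 200 resamples, then a
  sizing error); the intron-length *law* is therefore exact only for the
  sampler itself, and slightly truncated in placed genes. Tail-mass tests
  check the sampler.
- The exact mapper counts a palindromic placement (tag equal to its
  reverse complement) once, on the forward strand.
- Tag triage: a tag matching both the contaminant reference and the genome
  is contaminant — screening precedes mapping.
- k-mer ranking breaks count ties lexicographically, so top-n lists are
  total-order stable; tag tables sort by descending count then sequence.
- Premature-stop detection reports the first in-frame stop of the inclusion
  isoform when it precedes the skip isoform's first stop; no 50-nt NMD
  boundary rule is applied — the stop's codon index is reported so callers
  can apply one.
- Empty inputs: zero clones produce empty-but-valid outputs; an empty
  context list is a summary error; an empty DE table gives an all-zero
  summary.

## Nulls for motif controls

The uniform line `total/4^k` is the right reference for *displaying*
enrichment, but it is not a valid null for testing a control dinucleotide
on a motif-enriched tag set: the planted UG mass inflates the total window
count, so `total/16` over-states the chance level of every other
dinucleotide; a pooled composition-adjusted null is biased in the opposite
direction when tag groups differ in composition (the expectation of a
product is not the product of expectations across a mixture). The control
contrast is therefore made per tag: a one-tailed Welch comparison of
per-tag motif counts between site-derived and background tags — strongly
positive for UG, indistinguishable from chance for the GC-matched CA. On
composition-uniform random tags, UG and CA histograms are additionally
required to be KS-indistinguishable.

## Design choices where the design was open

- The built-in mapper is exact-match only; mismatch-tolerant alignment is
  delegated to external tools through the BED6 import path. The mapper
  exists to exercise the pipeline, not to compete with genome aligners.
- Gene models travel as BED12 (with the known/unknown flag in the score
  column) and GTF; both writers and the BED12 reader are direct
  implementations — the formats' line grammars are simple enough that a
  database-backed parser would add setup cost without benefit at this
  scale.
- Whether the "±" in published intron-geometry tables is SEM or SD is
  ambiguous; SEM is used (sample sd / √n) and both sd-bearing quantities
  are exposed so either can be recomputed.
- Distances are measured from the tag's proximal end, not its midpoint.
- The CLI is a thin veneer; every command is a few lines over the library
  functions, and all randomness funnels through the single seed in the
  simulation config.

## Problem sizes

Tests and the acceptance script run the simulator at desk scale (0.1–2 Mb
genomes, 15–60 genes, 200–500 clones, expression tables of 10³ genes),
chosen so a full suite run takes seconds while every count the analyses
rely on remains in the hundreds.

## Known limitations

- Exact-substring contaminant screening cannot flag divergent rRNA copies.
- Majority-overlap classification assigns boundary-straddling tags to a
  single category; a straddler classified "intron" that spans an
  exon–intron junction is excluded from geometry rather than truncated.
- One transcript per gene: overlapping isoforms are out of scope except in
  the explicitly constructed two-isoform RT-PCR/PTC analyses.
- The expression module consumes an upstream differential-expression
  table; it does not estimate expression or test significance itself.
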