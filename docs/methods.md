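# Methods

This note records the models, parameter choices and numerical conventions
behind `seroinkit`, and what the synthetic benchmark does and does not
demonstrate.

## The annotation model

A seroin precursor is modelled as a concatenation of modules
`A B1 C1 B2 C2 B3` (long form) or a class-specific subset thereof:

| class | allowed versions (module pattern) |
|-------|-----------------------------------|
| Sn1   | L = AB1C1B2C2B3, N = AB1C1B2, C = AB1C2B3 |
| Sn2   | L, C, T1 = AB1C1[B2C2]B3, T2 = A[B1C1]B2C2B3 (brackets = incomplete) |
| Sn3   | L, T = AB1C1B3 |

Module A is the secretion signal peptide (~20 residues); B modules are
conserved blocks enriched in Ala, Ser, Glu, Asp plus Lys/Arg; C modules
are short, diversified, Pro-rich linkers.  All coordinates in the package
are 0-based half-open.

### Signal peptide (module A)

`detect_signal` scans Kyte–Doolittle hydropathy in 8-residue windows over
residues 1–28; the A span is `[0, c)` with `c` = end of the longest run of
windows with mean > 1.5, plus 3, clamped to `[15, 30]`.  When no window
qualifies, `c` defaults to 20 and the annotation is flagged.  On synthetic
truth the prediction lands within ±2 of the true cleavage point; the ±4
tolerance asserted in tests leaves room for unusual tail compositions.

### B/C segmentation

`composition_profile` computes windowed residue-set fractions (window 15,
clipped at the edges).  Mature positions with Pro fraction ≥ 0.20 are
C-like; labels are majority-smoothed (window 7), runs shorter than 5
residues merge into the longer neighbour, and more than 3 B or 2 C runs
are merged at the weakest Pro-contrast boundary.  Thresholds (0.20 Pro,
window 15, min-run 5, smoothing 7) are package defaults exposed through
`PipelineConfig`; they are chosen so that linkers with ≥ half their
residues Pro are detected down to ~8 residues.

Threshold segmentation has a known, systematic bias: each B|C boundary
shifts ~3 residues into the B side (a window centred 3 residues inside a
B block already holds ≥ 3 Pro from the adjacent linker).  Version calling
de-biases observed lengths by this `BOUNDARY_SMEAR = 3` per adjacent
boundary before comparing them with canonical module sizes.

### Classification rules

Each class scores `satisfied clause weight / total weight`, motif clauses
weighing 2 and compositional clauses 1 (motifs are the sharpest single
piece of evidence):

* Sn1 — (i) a Trp at position 15–24 from the initial Met whose ±10
  neighbourhood is ≥ 25% charged (D/E/K/R); (ii) a 30-residue window with
  ≥ 20% Pro starting within 40 residues downstream of that Trp.
* Sn2 — (i) exact motif RYGG; (ii) Gly ≥ 20% over residues 20–50.
* Sn3 — (i) exact motif VYGE; (ii) a Trp at position 30–39.

"ca 20" and "ca 35" are rendered as the symmetric windows [15, 25) and
[30, 40).  A protein is assigned to the argmax class when its score
reaches `min_score = 0.5` with a margin ≥ `min_margin = 0.15`; ties and
sub-threshold sequences are reported `unclassified` (real curation worked
on pre-selected seroins, so the unclassified outcome is this package's
addition).  Clauses referencing positions beyond a short protein simply
evaluate false.

### Version calling and gene grouping

`call_version` matches the observed B/C run sequence against the class's
canonical patterns.  Positional labels (first B run = B1, …) are re-mapped
per candidate pattern, so e.g. the second B run of an Sn1 short form
becomes B3 under the C pattern.  Completeness of each slot is re-assessed
from the de-biased run length (complete iff ≥ 0.55 × the canonical full
length — segmentation flags can only demote); a completeness mismatch
costs 0.5, and candidates are ranked by mismatch cost with a small
log-length term (weight 0.01) breaking ties such as Sn1 N vs C, which
share the B-C-B shape and differ only in linker/block sizes.  A best cost
above 1 yields `unrecognized`.

`group_genes` single-links same-species isoforms that (i) share their
first k = 25 residues from the initial Met — the signal peptide is
retained by every splice version, so isoforms of one gene are identical
there, while paralogous genes diverge immediately — and (ii) reach
`id_threshold = 0.95` identity over their maximal near-identical local
block (identity scoring +1/−2, gap −3; a similarity matrix would creep
through compositionally biased but non-homologous modules and dilute the
measurement).  At most two genes per class are kept, mirroring the
observation that more were never seen; same-N-terminus non-overlapping
isoform pairs default to one gene, and a `genomic_splits` argument can
force the split when genome-level evidence exists (the silkworm Sn1-1 /
Sn1-2 situation, which also needed genomic sequence to resolve).

### Nomenclature

Names follow `abbrev + "Sn" + class + ("-" + gene)? + letter? + minor?`.
The abbreviation is the genus initial plus species-epithet letters,
extended until unique (`Bm`, `Ha`, `Has`).  Minor-variant digits start at
2 (the observed convention: `GmSn1B`, `GmSn1B2`).  Splice letters are
assigned per gene in descending version-group size with ties broken by
smallest member id — the original descriptions give no assignment rule, so
this deterministic convention is the package's own.  En-dashes from
typeset sources are normalised to ASCII hyphens on parse.

### Similarity and the sanity tree

Identity = matches / all alignment columns (gap columns included) of an
affine-gap global alignment (BLOSUM62, gap open 10, extend 1).  Since no
published definition of the similarity metric exists, the within- vs
between-class figures are treated as a qualitative ordering, which the
package reproduces (within ≈ 33–45%, between ≈ 21–26% on synthetic data).

The neighbor-joining tree is a sanity check, not a reimplementation of the
ML/Bayesian analyses.  Saitou–Nei with deterministic tie-breaking
(smallest label pair), negative branch lengths clamped to zero with the
deficit moved to the sibling, and the final node attached under the last
internal node with the full residual distance (so the 3-taxon example
d(A,B)=2, d(A,C)=d(B,C)=4 yields branches 1/1/3 exactly).  Monophyly is
tested on unrooted bipartitions.  The tree check runs on long-version
records only: a whole-length identity distance is meaningless between
isoforms differing by entire modules (an Sn3 long form is ~twice its short
form), which is the same reason the original phylogenetic analysis
restricted itself to character-based methods.

### Read quantification

Reads are translated in all six frames and locally aligned
(Smith–Waterman, BLOSUM62, gap 11/1) against each class's query — the 80
C-terminal residues of a class reference.  E = K·m·n·e^(−λS) uses
*ungapped* Karlin–Altschul λ and K applied to gapped scores, the classic
approximation; it overstates E and is therefore conservative at a fixed
threshold.  n is the translated read length (per-read E-values, not
library-wide; the original per-library search context is irreproducible
without the raw libraries).  λ solves Σ pᵢpⱼe^(λsᵢⱼ) = 1 by bisection to
1e−9; K uses the lattice-case series
σ = Σₖ (1/k)[E(e^(λSₖ); Sₖ<0) + P(Sₖ≥0)],
K = d·e^(−2σ) / (E[S·e^(λS)]·(1 − e^(−λd))), with the exact closed form
(p₊ − p₋)²/p₋ for {+1, −1} supports.  The implementation reproduces the
published ungapped BLOSUM62 values (λ = 0.3176, K = 0.134) and the
analytic λ = ln 3 for +1/−1 scoring.

A note on the e−20 threshold: 30 identical residues of the Ala/Ser/Glu/Asp-
rich seroin C-terminus score ~140 (λS ≈ 45, E ≈ 1e−17), so 90-nt reads
cannot clear e−20 even as perfect matches; ~50 identical residues are
needed.  The default read length is therefore 150 nt, comfortably inside
the 2×250 nt MiSeq and ~400 nt pyrosequencing reads of the libraries this
protocol emulates.

## The synthetic generator

The generator is the package's study condition, not a tuning knob.  Each
class/module has a fixed composition (B: ~72% A/S/E/D with ~44% charged;
Sn2 B1: 35% Gly; C: 60% Pro; Trp frequency 0 everywhere outside planted
anchors, because Trp position is the diagnostic signal), filled by exact
quota and shuffled.  Within a class, B/C modules derive from fixed
class-level template blocks mutated per record at rate 0.4 — the
"conserved blocks" picture — which produces the within- vs between-class
identity ordering by construction.  Module lengths are drawn uniformly
from ranges transcribing the qualitative size statements for each class
(e.g. Sn1: short B1 of 10–20, well-developed C1 of 25–40, large B2 of
45–60; Sn2: Gly-rich B1 of 30–50 and a B3 of 90–100; Sn3: B2+C2 ≈ 120–150
present only in the long form); totals respect the ~250-residue cap on
mature proteins, except Sn3 long forms which necessarily exceed it
slightly (N/C termini of ~60 plus a ~140-residue centre).  Incomplete
(bracketed) modules retain their N-terminal part at the smallest
compositionally resolvable size (B ≥ 15, C = 8 residues) — below ~15
residues a window-15 profile cannot separate a B block flanked by
Pro-rich linkers at all.  Class anchors are planted verbatim: Sn1
`WEKDE` at B1 offset 0–2 (placing Trp at 18–24 with six charged
neighbours, the last two contributed by the signal-peptide tail), Sn2
`RYGG` at B1 offset 4–8 (surviving even the truncated T2 B1), Sn3 a Trp
at absolute position 32–36 plus `VYGE` later in B1.  Short C linkers get
their Pro quota enforced post-mutation (the generator's contract is that
C modules are unambiguously Pro-rich).

cDNAs are back-translations with uniformly random synonymous codons,
random UTRs (defaults 40/60 nt), an in-frame stop forced at the end of the
5′ UTR, and deterministic re-drawing in the rare case a spurious
shifted-frame ORF would outrun the intended one.  Reads are uniform
substrings of weighted transcripts, strand 50/50, with optional
substitution errors.

What passing the synthetic benchmark shows: the rules, segmentation,
version logic, statistics and bookkeeping are implemented correctly and
are mutually consistent at realistic sequence scales.  What it does not
show: performance on real transcriptomes, where module boundaries are
fuzzier, compositions drift continuously between classes, signal peptides
vary more, assemblies contain frameshifts and chimeras, and diagnostic
motifs are present in only ~half to three-quarters of class members.  The
unclassified outcome and all exposed thresholds exist precisely for that
setting.

## Problem sizes and determinism

The shipped checks use 300-record datasets (100 per class over all splice
versions), 60-record similarity samples (20 per class), 30-leaf trees
(10 long-version records per class), 50 random 8-leaf additive matrices,
and 1,000 planted plus 1,000 random 150-nt reads — sizes at which every
statistic above is stable across seeds while the whole suite runs in
seconds.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical outputs,
including the pipeline report (records, summaries, provenance digest).

## Known limitations

* Single-sequence segmentation only; no alignment- or HMM-based
  refinement of module boundaries.
* The classifier is exactly the published rule set made explicit; it will
  under-call classes whose diagnostic motifs are absent (a third of real
  Sn2/Sn3 members lack RYGG/VYGE) unless the compositional clauses fire.
* Gene grouping is sequence-only; true paralogs with identical N-termini
  are merged unless genomic evidence is supplied.
* Ungapped E-value statistics applied to gapped scores; per-read database
  length.  Absolute E-values are conservative, rankings unaffected.
* The NJ tree is a distance-based sanity check on long isoforms, not a
  substitute for ML/Bayesian phylogenetics.
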