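# Methods

## The problem and the model

A bulk RNA-seq assembly of a symbiotic coral is a *metatranscriptome*:
host (cnidarian) and symbiont (*Symbiodinium*) transcripts are
interleaved in one sequence set. `holopart` separates them using two
orthogonal signals and profiles the result.

**Signal 1 — reference-database hits.** Each transcript carries zero or
more tabular alignment hits, each labelled `host_db` or `symbiont_db`.
At an e-value cutoff *t*, a transcript with passing hits to exactly one
database is assigned to that origin; passing hits to both make it
*ambiguous*; no passing hit makes it *holobiont-specific*. The cutoff is
selected by sweeping an ordered set (default 1e-4, 1e-5, 1e-8, 1e-10)
and keeping the cutoff that minimises the unclassified count; exact ties
resolve toward the most stringent (smallest) cutoff, a conservative
choice made here because no tie rule is forced by the procedure itself.
Cutoff comparison is inclusive (`evalue <= t`), the standard BLAST
filtering convention.

**Signal 2 — oligonucleotide composition.** Host and symbiont
transcripts differ systematically in base composition (GC modes near
0.43 and 0.54 in this system). Ambiguous transcripts are resolved by a
linear maximum-margin classifier (LinearSVC, squared-hinge, fixed
regularisation C = 1.0) over relative k-mer frequencies, k = 4, with
counts pooled over the sequence and its reverse complement and
normalised to sum to one. Training material is the exclusive-hit bins
themselves — the classifier is self-supervised by signal 1, the same
design as psytrans-style segregation. A held-out accuracy from a
deterministic 80/20 stratified split is recorded with the model; below
20 training sequences per class training refuses and the pipeline falls
back to best-hit resolution for ambiguous transcripts. The model is
stored as explicit weights + bias over the lexicographic 4^k feature
order, so decisions are reproducible independent of the fitting library.

Final bins merge classifier-resolved ambiguous transcripts into
host/symbiont before all downstream reporting; assignments are always
exhaustive and disjoint, and provenance (`exclusive_hit | classifier |
no_hit`) is kept per transcript.

## Preprocessing rules

- **Trimming** (Phred scale): HEADCROP 10 → LEADING 30 → TRAILING 30 →
  SLIDINGWINDOW 4:20 → MINLEN 30, applied in that order. The sliding
  window scans 5'→3' and cuts the read at the *start* of the first full
  window whose mean quality falls below the threshold; windows shorter
  than the window size are not evaluated; survivors must be strictly
  longer than the minimum length. These step details are not uniquely
  determined by the published tool's one-line description; the choices
  here are fixed, documented, and verified against an independent
  rule-replay oracle.
- **Length filter**: keep length ≥ 300 bp (the boundary is treated as
  inclusive).
- **ORFs**: the single longest ATG-to-stop ORF over all six frames, with
  peptide length ≥ 100 aa counting the initial M (configurable).
  Partial (start- or stop-less) coding regions are excluded — the
  simplest defensible rule; a Markov-model coding-potential score is
  deliberately out of scope.
- **Clustering**: greedy incremental, longest-first; identity = maximum
  global-alignment matches (equivalently the longest common subsequence)
  divided by the shorter sequence's length, the CD-HIT convention; a
  peptide joins the first representative reaching the threshold (0.95)
  else founds a cluster. The shared-word prefilter (word size 10) is
  applied only where a counting bound proves that the threshold is
  unreachable without a shared word — with m = ⌈0.95·L⌉ required matches
  over shorter length L, no-shared-word caps matches at
  (L − m + 1)·(w − 1) — so filtered and unfiltered clustering are
  provably identical, and this is also property-tested. (Note: word
  size 10 is unusually large for protein clustering at 95 % — CD-HIT's
  own default is 5 — but it is kept as configured.)
- **N50**: the largest length L such that sequences of length ≥ L hold
  at least half the total bases (descending cumulative-sum crossing).
- **GC fraction**: (G+C) / (A+C+G+T), case-insensitive; ambiguity codes
  are excluded from the denominator, and a sequence with no unambiguous
  bases has undefined GC (reported missing).

## Enrichment and reporting

- **Term enrichment**: classic per-term one-sided Fisher exact test; the
  p-value is the hypergeometric upper tail P(X ≥ a) via
  `scipy.stats.hypergeom.sf`. Significance is flagged at raw p < 0.05
  with no multiplicity correction — the convention used for descriptive
  per-bin GO summaries — and a Benjamini–Hochberg column is emitted as
  supplementary output only. GO-graph decorrelation (topGO's elim /
  weight algorithms) is intentionally not implemented: the flag mirrors
  the classic per-term test. The default background is the whole
  metatranscriptome (configurable); the focal set must be a subset of it.
- **Domain matrix**: cell = log10(1 + 10 000 · count / n_peptides),
  i.e. domain occurrences per ten thousand peptides on a log scale. The
  constants are fixed here for reproducibility since "normalised,
  log-transformed" admits many conventions; duplication-invariance (the
  matrix is unchanged when every peptide is duplicated) is the property
  that matters and is tested. Row selection takes the top 30 domains by
  Fisher enrichment of the focal column against all others pooled.
- **Percentages**: every reported percentage is round-half-away-from-zero
  of 100·num/den, and the report always carries the numerator and
  denominator so each percentage is recomputable.
- **Ortholog groups**: groups with fewer than 3 total members are
  dropped *before* subset assignment (filter-then-partition); each
  surviving group is counted in exactly one taxon subset — the exact set
  of taxa with ≥ 1 member — so subset counts always sum to the filtered
  group count. Scleractinians are one composite taxon.
- **Pathway coverage**: per KEGG pathway, each KO falls in exactly one
  of five categories — `both` (host ∧ symbiont, regardless of the
  specific bin), `host`, `symbiont`, `specific` (only when neither host
  nor symbiont carries it), `unrepresented` — and percentages use the
  full pathway KO list as denominator, so the five always sum to 100
  exactly as rationals. Only presence matters; transcript multiplicity
  never changes a category.

## The synthetic holobiont

The generator emulates the statistical structure the analysis relies on,
not sequencing realism:

- **Transcripts**: i.i.d. bases with P(G) = P(C) = gc_target/2 (order-0;
  GC is the one composition signal a reader can verify), lengths from a
  log-normal (median ≈ 1 kb) clipped to [300, 3000] bp. Host gc_target
  0.43, symbiont 0.54 — the per-origin GC modes of this system.
- **Reads**: uniform-start fragments, mate 2 reverse-complemented,
  Gaussian or constant qualities in Phred+33.
- **Hit tables**: with per-origin probability `p_nohit` a transcript is
  masked (no hits); otherwise it hits its own database with conditional
  probability `p_hit_true` and, independently, the other database with
  probability `p_hit_cross`. E-values are log10-uniform on a
  configurable range (default [−50, −3], independent of origin — the
  sweep is exercised without modelling alignment biology).
- **Demo conditions**: 2,000 transcripts per origin; `p_hit_true` = 1;
  per-origin no-hit rates 0.52 (host) and 0.42 (symbiont), which plant
  overall bin fractions 0.24 / 0.29 / 0.47 at equal origin counts;
  cross-hit rate 0.12 so the classifier has real work; demo e-values on
  [−50, −5] so every emitted hit passes the most permissive examined
  cutoff — with the wider default law a few percent of single-hit
  transcripts would fall above 1e-4 and leak into the specific bin,
  decoupling the planted fractions from the recovered ones.
- **Planted structure**: annotation tables can plant per-pathway KO
  categories and ortholog tables an exact taxon-subset partition; both
  are exactly recoverable downstream, which is what the structure-
  recovery tests assert.
- **Seeding**: one master seed; each stage derives seed + stage-index.
  Identical seeds give byte-identical outputs.

What passing these tests shows — and does not. The generator's
transcripts are compositionally ideal (i.i.d. bases at exactly the
target GC), so classifier accuracies near 1.0 here are an upper bound;
real transcripts have codon structure, repeats, UTR heterogeneity and
within-genome GC variance that narrow the margin. The hit model contains
no alignment biology (no homology structure, no e-value/origin
correlation), so the sweep's behaviour on real data depends on database
completeness in a way these tests cannot probe. What the tests do
establish is that every deterministic rule (binning, sweep, filters,
ORFs, clustering, enrichment arithmetic, Venn and coverage partitions)
is implemented exactly as specified, verified against independent
brute-force oracles.

## Problem sizes and numerical choices

The shipped demo and the acceptance script use 4,000 transcripts
(2,000 per origin) and ~7,500 planted ortholog groups — sizes at which
every statistical check (3-binomial-SD recovery, ≥ 0.95 classifier
accuracy) is well-powered while a full run completes in seconds on one
CPU. Oracle-equivalence suites use 1,000 random small inputs per
primitive. Histogram modes use bin width 0.01 with no kernel smoothing,
matching the ~1 % resolution at which GC modes are quoted; the mode is
the midpoint of the highest-mass bin (ties: lowest bin, via argmax).
Fisher p-values are clipped to [0, 1]; sweep tie-breaks, cluster
tie-breaks (input order at equal length) and ORF tie-breaks (+ strand,
lower frame, leftmost start at equal length) are all fixed and tested.

## Known limitations

- Only two origin classes; a third genuine source (e.g. other microbiota)
  is absorbed by whichever signal it resembles.
- The composition classifier is linear over 4-mers; origins with
  overlapping GC/k-mer distributions (separation ≲ 0.04 GC) will not
  reach the accuracies seen in the demo.
- Greedy clustering is O(n·clusters) alignments; it is meant for
  peptide-set deduplication at desk scale, not millions of sequences.
- No GO-DAG propagation, no KEGG module-completeness scoring, no
  assembler, no external aligner execution — alignment results are
  consumed, never produced.
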