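# Methods

This note documents the models, defaults and design choices behind
`transqc`, and what its simulator-based validation does and does not
demonstrate about real data.

## Consistency indexes

**ICI.** The internal index asks how faithfully an assembler's consensus
represents the reads it claims to contain. For read *r* with contig
consensus *c*, `ICI(r) = 100 · m(r,c) / |r|`, where `m(r,c)` counts matched
bases in the best local alignment of *r* vs *c* over both strands, and the
denominator is the *full* read length. The full-length denominator is
deliberate: it makes ICI = 100 equivalent to "the entire read mapped at
100% identity", and penalizes consensi that only partially accommodate
their members. A read with no positive-scoring alignment contributes 0.
Assembly-level ICI averages over clustered reads only; singletons are
excluded because each would score a trivial 100 against itself and, with
singletons typically outnumbering clustered reads five-fold, would flatten
any difference between assemblers. ICI is monotone non-increasing in the
number of consensus errors, which is what makes it usable as a ranking key.

**ECI.** The external index asks the complementary question: has the
assembler split one gene across several contigs? For two contigs,
`ECI = 100 · identity_frac · aln_cols / min_len`, capped at 100.
Normalizing by the shorter contig makes containment — a short contig lying
wholly inside a longer one at perfect identity — score 100, which is
exactly the redundancy case. Each contig reports its best-scoring partner;
scores above the merge threshold (default 75, the conventional cutoff for
"these consensi represent the same gene") are flagged. Contigs with no
positive alignment to any partner contribute 0 to the mean rather than
being dropped, so an assembly of mutually unrelated contigs has a mean ECI
near 0, not an undefined one. Averaging is per contig (best partner), not
per pair; with best-partner semantics every contig contributes exactly
once.

**Ranking.** `evaluate_assemblies` orders candidates by mean ICI
(descending), then by the number of unigenes with a passing hit against a
curated protein database, then by mean ECI (ascending), then by name for
determinism. Candidates without a hit table sort below any candidate with
one on the annotation key; all three criteria are reported so a user can
override the verdict.

## Local alignment engine

Both indexes reduce to optimal local alignments, computed exactly
(Smith–Waterman/Gotoh) rather than heuristically: at QC scale the inputs
are a few hundred reads and a few thousand contig pairs, and exactness
makes every downstream number reproducible and testable.

* Scoring: match +1, mismatch −2, affine gaps (first gap column −3, each
  further column −1). The downstream metrics depend only on identity and
  coverage fractions, which are robust to the exact scheme; the parameters
  are exposed (`AlignParams`, `RunConfig`) for sensitivity checks.
* `N` scores as a mismatch and never counts as a matched base.
* Among co-optimal alignments the engine maximizes the matched-base count
  as a secondary objective. Score alone does not pin down identity (paths
  can trade matches against gap columns at equal score), and ICI depends on
  identity, so the reported `(score, n_ident)` must be a function of the
  inputs. Implementation: the DP runs over integers `score·2^20 + n_ident`;
  lexicographic comparison coincides with numeric comparison and both
  components are additive along a path. Remaining ties (spans) resolve to
  the smallest end coordinates, query-major; strand ties resolve to plus.
* The forward pass is vectorized per row (numpy). The within-row horizontal
  gap recurrence is replaced by a running prefix maximum, valid because
  re-opening a gap immediately after closing one can never beat extending
  it (gap open ≤ gap extend).
* An optional k-mer prefilter (`prefilter_k=11`) skips pairs sharing no
  exact 11-mer on either strand. Skipped pairs can only have short, weak
  alignments, but the filter does change "no alignment" answers for them,
  so it is off by default and off everywhere a test asserts exact scores.
* Alignments scoring below one match are reported as absent.

## Read cleaning

Masking is a bounded-mismatch sliding-window scan of each adapter and its
reverse complement: full-length adapter windows anywhere in the read, plus
partial overlaps of at least `min_match` (default 10) bases hanging off
either read end, with a mismatch budget of `floor(0.1 · overlap)`. Adapters
shorter than `min_match` must match in full. This is intentionally not a
Smith–Waterman screen: library adapters are short, known sequences, and a
windowed Hamming scan is deterministic and directly testable against a
brute-force count. Overlapping masks are merged.

Clipping keeps the longest maximal run of unmasked bases (ties: the
5'-most run, for determinism), appending `/clip` to the read id; reads
whose best run is shorter than `min_len` (default 20 — permissive, because
a well-behaved library loses almost nothing to cleaning) are removed and
counted. Clipping an already-clean read is the identity, so the operation
is idempotent.

## Annotation and coverage

* E-value filtering is inclusive at 1e-5 by default.
* Best hit per query: highest bit score, then lowest e-value, then subject
  id — a total, deterministic order.
* Subject coverage merges the subject-side intervals of one query's HSPs
  (half-open arithmetic internally; the tabular 1-based inclusive
  convention at the file boundary) and divides by subject length.
* Full-length calling counts subjects whose *best single query* covers at
  least the threshold (default 0.90, inclusive: exactly 90% counts). HSPs
  of different queries are never merged in this mode — two half-covering
  unigenes do not make a full-length gene, since neither transcript is
  itself complete. A union-across-queries mode exists behind a flag for
  the looser reading of "covered by unigenes".
* Keyword tallies over best-hit descriptions use case-insensitive substring
  patterns; a query may count toward several gene families.

## SSR detection

Perfect tandem repeats of primitive 2–6 base motifs, with per-class
minimum unit counts `{di: 6, tri: 4, tetra: 3, penta: 3, hexa: 3}` — the
conventional MISA-style defaults for transcriptome marker scans, exposed in
configuration. Mononucleotide runs are excluded by design: in
pyrosequencing data they are dominated by homopolymer over/undercall
artifacts rather than genuine microsatellites, and the marker-candidate
step exists precisely to dodge sequencing-error loci. Candidate runs are
enumerated at every start position, extended in whole units, and resolved
leftmost-first then longest — note this means a run whose phase-shifted
copy starts one base earlier (e.g. `T·ACGT·ACGT…` read as `TACG` repeats)
is reported in that leftmost phase. Loci never overlap; reported spans are
always whole-unit multiples of the motif. Canonical motifs are the
lexicographic minimum over all rotations of the motif and of its reverse
complement, so complementary-strand and phase variants tally together; this
is a stated convention, not a claim of bit-for-bit agreement with any
particular external SSR tool. Marker candidates are the SSR-bearing
sequences that also carry a functional annotation — annotating a random
sequencing error is unlikely, so these are the loci worth genotyping.

## Simulator: what it emulates, and what it does not

The generator produces, under a single integer seed and with pure integer
RNG (byte-identical across platforms):

* transcripts — i.i.d. sequences, default GC 0.40, lengths 300–2,000;
  pairwise shared-11-mer count capped (default ≤ 8 per pair, 0 on request)
  so that unrelated transcripts stay unrelated under alignment;
* reads — substrings of transcripts on either strand, Gaussian length
  around 554 bases (the clean-read average the toolkit's target projects
  report), optionally flanked by full adapters, optionally corrupted by a
  454-style error model: per-homopolymer ±1-base over/undercall plus
  uniform substitutions;
* assembly variants with exact truth — `truth` (consensus = transcript),
  `split` (first/last 85% fragments, ~70% mutual overlap, so each split
  pair scores ECI ≈ 100·0.70/0.85 ≈ 82, safely above the merge threshold),
  `mutated(p)` (i.i.d. consensus substitutions), and `shuffled` (reads
  reassigned at random; negative control);
* planted SSR records (class mix defaulting to the observed transcriptome
  frequencies: tetra 35.7%, penta 30.8%, tri 16.3%, hexa 13.4%, di 4.0%),
  each validated at generation time to contain exactly its planted locus;
* planted tabular hit files whose per-(query, subject) merged coverage is
  exact to the residue and whose bit scores decrease with e-value.

Default scales are roughly 1/100 of a full 454 transcriptome project
(the `full` preset: 46 transcripts, 950 reads; `smoke`: 12 and 120), which
keeps any pipeline run in minutes on one core.

What the simulator does **not** model: flowgram-level 454 noise, CAFIE
hybrid reads, quality values, chimeras, paralogy and genuine gene families,
expression-level read depth variation, and polymorphism between reads of
one gene. Consequently, passing the simulator-based suite shows the
*computations* are correct and the metrics respond to consensus error,
redundancy and shuffling as designed — it does not show that any particular
real assembly is good, nor that the indexes separate real assemblers by the
same margins as the synthetic variants.

## Numerical choices and degenerate inputs

* Intervals are 0-based half-open internally; tabular formats keep their
  native 1-based inclusive convention, with subject spans normalized to
  `sstart ≤ send` plus a strand flag on load and re-reversed on write.
* Percentages in summaries are rounded to 2 decimals (annotation
  percentages to whole points, matching the precision such tables are
  reported at); means are exact doubles internally.
* Assemblies with no contigs are an error for ICI ("nothing to score");
  a single contig yields a zero ECI result with a logged warning.
* Empty hit lists, empty locus lists and empty files yield empty/zero
  results, not errors; duplicated FASTA ids, conflicting membership rows,
  out-of-bounds subject spans and wrong column counts are hard errors with
  the offending id or line number.
* Report writers emit no timestamps; reruns from a saved `RunConfig` are
  byte-identical.

## Open design points, resolved

* The exact historical ICI/ECI formulas were published outside the sources
  available here; the definitions above satisfy every stated anchor (100 =
  entire read at full identity; self-alignment = 100; >75 means one gene
  split across contigs; "average overlap size and identity") and are
  documented as this package's definitions.
* Whether historical clipping kept the largest or the 5'-most unmasked
  substring is not recoverable; largest is implemented (with the 5'-most
  tie-break), matching the "bigger substring" naming of such scripts.
* Assembly-level ECI averages per contig over best partners, not over all
  pairs.
* Quality values are never consumed: cleaning operates on FASTA after
  upstream extraction, and nothing downstream uses base qualities.

## Known limitations

* O(n·m) exact alignment makes all-vs-all ECI quadratic in contig count;
  beyond ~10³ contigs enable the k-mer prefilter or subsample.
* The aligner's scoring scheme is a fixed default, not a fitted model of
  454 error; ICI values shift by fractions of a point under other
  reasonable schemes.
* SSR detection covers perfect repeats only (no compound or interrupted
  microsatellites), and the canonical-motif convention may group motifs
  differently from other SSR software.
* ACE support reads membership (`CO`/`AF` lines) only; per-base ACE
  alignments are ignored.
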