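# transqc

Reference-free QC and gene-discovery utilities for *de novo* transcriptome
assemblies built from clustering-style assemblers (CAP3, MIRA, Newbler and
kin), aimed at projects on non-model organisms where no reference genome
exists to map back against — the situation of a typical 454/long-read EST
survey of an invasive mollusc, a non-model plant, or any first
transcriptome.

## What it computes

When several assemblers produce competing unigene sets (contigs +
singletons), `transqc` scores them from two independent directions and ranks
them:

* **Internal Consistency Index (ICI)** — for each read *r* assembled into a
  contig with consensus *c*,

  `ICI(r) = 100 · m(r, c) / |r|`

  where `m(r, c)` is the number of matched bases in the best local alignment
  of *r* against *c* (either strand). A read mapped end-to-end at 100%
  identity scores 100; mismatches, indels and unaligned read tails all lower
  the score. The assembly-level ICI is the mean over all clustered reads
  (singletons are excluded — each would trivially score 100 against itself
  and swamp the signal).

* **External Consistency Index (ECI)** — for contigs *a*, *b* with
  best local alignment of identity fraction *id* over *L* columns,

  `ECI(a, b) = 100 · id · L / min(|a|, |b|)`, capped at 100.

  A contig duplicated verbatim, or contained in another at perfect identity,
  scores 100; unrelated contigs score near 0. Per contig the best-scoring
  partner is reported, and scores above a merge threshold (default 75) flag
  consensi so similar that one gene has probably been split across contigs.

* Ranking: highest mean ICI, then most unigenes annotated against a curated
  protein database (inclusive e-value cutoff 1e-5, best hit = highest bit
  score), then lowest mean ECI.

Around that core the package provides adapter masking and
largest-unmasked-run read clipping, best-hit annotation summaries,
interval-union subject coverage with “full-length” gene calling (a reference
protein covered ≥ 90% by a single unigene), perfect-SSR detection (di- to
hexanucleotide, canonical-motif grouping) with annotated-marker-candidate
extraction, reads-per-contig histograms, and a fully seeded 454-style
simulator that generates ground-truthed inputs for all of the above. The
local aligner is an exact affine-gap Smith–Waterman (`+1/−2`, gap open `−3`,
extend `−1`) with a deterministic identity tie-break; see
`docs/methods.md`.

## Worked example

Simulate a small ground-truthed dataset, then score the truth assembly:

```bash
$ transqc simulate --preset smoke --seed 7 --outdir demo
simulate: wrote smoke dataset (seed 7) to demo

$ transqc ici --assembly demo/unigenes_truth.fa --reads demo/reads.fa \
              --membership demo/membership.tsv --out demo/ici.tsv
ici: mean 100.00 over 120 reads

$ transqc eci --assembly demo/unigenes_truth.fa \
              --membership demo/membership.tsv --out demo/eci.tsv
eci: mean 3.85, 0 contig(s) above 75.0

$ head -3 demo/eci.tsv
CONTIG_ID	BEST_PARTNER	ECI	FLAGGED
t0000	t0004	3.33	no
t0001	t0002	4.31	no
```

The mean ICI of exactly 100 says every simulated read maps back onto its
consensus end-to-end at perfect identity — the expected anchor for an
error-free truth assembly. The low ECI values (best-partner similarity ~3–4
out of 100) say the contigs are mutually unrelated: no redundancy, nothing
flagged for merging. A mutated or split assembly of the same reads scores
visibly worse on ICI or gets flagged by ECI, which is what drives the
`transqc evaluate` ranking.

Other entry points: `transqc clip`, `transqc annotate-summary`,
`transqc fulllength`, `transqc ssr`, `transqc evaluate` — see `--help` on
each.

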