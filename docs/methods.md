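# Methods

## Problem setting

Draft genome assemblies of non-model organisms are typically annotated from
two evidence tracks: spliced protein-to-genome alignments of a related,
well-curated proteome ("homology" models, e.g. exonerate `protein2genome`
output) and open reading frames extracted from de novo assembled RNA-seq
transcripts ("transcript" models). The union of both tracks is highly
redundant — alternative isoforms, duplicate homology placements (aligners
are often run with `--bestn 2` to catch paralogs), and transcript fragments
pile up at each locus. `nrannot` reduces this joint annotation to one
representative gene model per locus and provides the evaluation machinery
used to audit the result across a clade: BUSCO presence/absence pattern
analysis, best-reciprocal-hit (RBH) rescue of apparently missing orthologs,
and alignment-metric matrices.

## Non-redundant selection

Let each gene model be an ordered set of exons on one strand of one
sequence, with ORF length `floor(total CDS bp / 3)` amino acids. The
selection procedure is:

1. Strands are fully independent throughout.
2. Every exon start and every exon end coordinate is assigned to a window of
   `window_size` bp (default 100; the window index of a 1-based coordinate
   `c` is `floor((c - 1) / window_size)`). Window coverage is the number of
   boundary features assigned to the window; a start and an end in the same
   window count twice. Coverage is computed over **all** input models,
   including those that fail the filters below — filtering applies at
   choice time only.
3. Windows are visited in order of decreasing coverage. At each window, the
   still-live model whose gene span (first exon start to last exon end)
   intersects the window, passes both filters (ORF >= `min_orf_aa`, default
   60 aa; exon count >= `min_exons`, default 3) and has the longest ORF is
   selected; every other live model whose gene span intersects the *chosen
   model's* span is discarded. Windows whose candidates are exhausted are
   skipped. A selected model is never revisited or displaced.

The exon/ORF floors exist to keep partially assembled transcript fragments
and spurious short ORFs from inflating the gene count; they are tuned for
gene-dense genomes with many exons per gene (nematodes) and may be
inappropriate for taxa with fewer exons per gene — both are parameters.

### Design choices the procedure description leaves open

* **Discard radius.** "Discard the other intersecting models" can mean
  models intersecting the *window* or models intersecting the *chosen
  model*. Discarding by window would delete non-competing neighbours that
  merely touch a gene-dense window, so the default radius is the chosen
  model's gene span; `discard_scope="window"` exposes the stricter variant
  and the audit log records every decision either way.
* **Span vs exon intersection.** Overlap tests for discarding use gene
  spans, not exon-level intersection: competing isoforms interleave introns,
  and span overlap is the conservative reading. Exon-level disjointness of
  the selected set follows and is asserted in the tests.
* **Tie-breaks.** Window order ties break by (seq_id, strand with `+`
  first, window index ascending); candidate ties by (longest ORF, smaller
  gene start, smaller model id). The underlying procedure is order-dependent,
  so explicit total orders are required for reproducible annotation.
* **Terminal sweep.** In principle every eligible model is reachable through
  the windows its own boundaries define; however a model can lose all its
  windows to higher-ORF candidates that do not overlap it and remain
  undecided. A deterministic post-pass (models in (seq_id, span start,
  model_id) order) selects leftover eligible models that overlap no selected
  model and assigns final discard reasons. Every input model therefore ends
  up exactly once in `selected` or `discarded` (with reason
  `overlap_with_selected`, `filter_exons` or `filter_orf_len`; a model
  failing both filters reports the exon reason).
* **Threshold monotonicity.** Lowering `min_orf_aa` cannot shrink the
  selected set's total ORF length on inputs where competing models are
  nested within their locus winner (the fixture regime, where it is tested).
  It is not a theorem for arbitrary inputs: a newly eligible short model can
  win an otherwise-empty window and discard a long overlapping model whose
  own windows come later in the coverage order.

## ORF extraction

Transcript evidence is prepared by scanning all six reading frames for
maximal stop-free stretches of at least `min_len` amino acids (default 40,
stops excluded from the count). ORFs may be "partial": they need not start
with ATG and need not end at a stop, because assembled transcripts are
frequently truncated. The standard genetic code is used (nematode nuclear
genes); codons containing N or another IUPAC ambiguity symbol translate to
`X` and never terminate an ORF. The `complete5p` flag is set when an ORF
starts with Met or abuts the transcript edge, `complete3p` when it ends at a
stop or the edge; both interpretations of "complete" are thereby exposed to
downstream consumers rather than filtered on.

## Ortholog audit

* **Presence matrix.** A gene is present in a genome iff any of its BUSCO
  rows has status Complete or Duplicated (Fragmented counts as absent by
  default; configurable). Row bitstrings are tallied; the top 20 patterns
  summarize the clade. Dominant patterns separate systematic effects (a
  problematic assembly, lineage-wide loss, pipeline detection failure) from
  the low-frequency noise expected of random misannotation.
* **RBH.** Hits with e-value >= 1e-4 are removed (strict inequality); the
  best hit per query is the highest bitscore (ties: lower e-value, then
  smaller subject id); multiple HSPs of one query-subject pair are
  represented by their best-scoring row, never summed. A pair is reported
  iff mutual.
* **Rescue.** Genes missing in all genomes whose mapped reference protein
  has an RBH partner in every genome are "rescued" — evidence that the
  completeness pipeline, not the annotation, failed to detect them. Genes
  without a protein mapping are excluded from the denominator and listed.
* **Metrics.** Five matrices per gene set: bitscore, alignment length,
  percent identity, normalized bitscore (bitscore / alignment length) and
  aligned proportion (alignment length / reference query length). Absent
  cells are NaN, never zero. `subsample_matched` draws seeded
  without-replacement replicates so unequal gene sets are compared at a
  common size.

## Synthetic data

The generators produce the study conditions for every test and for
`scripts/acceptance.py`:

* **Locus sets** (`gen_locus_set`): 2–6 models per locus on 1–3 toy
  sequences, both strands. Each locus has one intended winner (3–5 exons,
  80–200 aa ORF) and decoys drawn from the four redundancy classes seen in
  practice: shorter eligible isoforms, 2-exon fragments, sub-60-aa ORFs,
  and duplicate homology placements sharing the winner's source protein.
  Decoy spans are strictly nested inside the winner's span and loci are
  spaced more than two windows apart, which makes the planted winner the
  provably unique correct answer; `tie_mode` plants exact ORF ties to
  exercise the tie-breaks. Model coordinates, not genome sequence, drive
  the selector, so the toy genomes carry no sequence.
* **BUSCO tables** (`gen_busco_tables`): full_table files realizing planted
  pattern frequencies exactly, with optional Duplicated-row injection.
* **BLAST tables** (`gen_blast_tables`): bipartite outfmt-6 tables where a
  chosen fraction of reference proteins get planted mutual-best partners
  (strict bitscore maxima), plus confounders: one-way bests, mutual pairs
  at e-value 1e-3 (above the cutoff) and extra lower-scoring HSP rows.

What the generators do **not** emulate: genuine sequence divergence and its
decay of alignability, alignment errors of real spliced aligners
(frameshifts, split codons — spans are taken verbatim), fragmented
assemblies, and the size of real gene complements. Passing tests therefore
demonstrate algorithmic correctness of selection, extraction and auditing on
inputs with known truth — not annotation quality on any real genome.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive exactly as in GFF; the only half-open
conversion lives inside the interval index. ORF lengths use integer floor
division; stop codons are not subtracted. Empty inputs yield empty results
(not errors); a file with no GFF dump section, or an mRNA without CDS/exon
children, warns and is skipped. All randomness flows through
`numpy.random.default_rng(seed)`; logs carry no timestamps, so repeated runs
are byte-identical. Problem sizes in the test suite and acceptance script
(1,000 loci for selector/oracle agreement and winner recovery, 200
transcripts for the ORF oracle, 200x200 proteomes for RBH, 10,000
subsampling replicates) were chosen to exercise every code path with
comfortable statistical resolution while keeping the whole suite around ten
seconds.

## Known limitations

* The selector is greedy with no backtracking; it inherits the order
  dependence of the underlying procedure, made reproducible rather than
  optimal by the documented tie-breaks.
* ORF length is span-derived (`floor(CDS bp / 3)`); proteins are never
  re-translated from genome sequence, so aligner-introduced frame errors go
  unnoticed.
* The exonerate reader consumes only `gene`/`exon` rows of GFF dump
  sections; alignment detail rows (`similarity`, splice sites) are ignored.
* Only the two-column busco-id-to-protein mapping is supported for rescue;
  OrthoDB itself is not parsed.
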