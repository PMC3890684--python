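# Methods

## Identification model

A query sequence is identified by the *best close match* rule: among all
admissible reference sequences, keep those whose percent similarity to the
query is **strictly greater** than a threshold *t* (default 99, i.e. a
p-distance strictly below 1%) over a comparable overlap of at least
`min_overlap` sites (default 600).  The identification is `NO_MATCH` if
that set is empty, `UNAMBIGUOUS` if it contains exactly one species name,
and `AMBIGUOUS` otherwise.  The strict inequality matters: a reference at
exactly 99.0% similarity (1 mismatch in 100 comparable sites) is *not* a
candidate.

Similarity is `100·(1 − m/L)` where *m* counts mismatches over the *L*
sites at which both sequences show an unambiguous base (`A/C/G/T`).  Sites
with gaps or IUPAC ambiguity codes in either sequence are excluded
(pairwise deletion), matching the default of the standard distance
software for Sanger-era barcode data.  `m`, `L` and every derived quantity
are exact integers/rationals (`fractions.Fraction`).  This is not
pedantry: the evaluation flags a **tie** when the best correct and the
best incorrect candidate are *exactly* equally similar, and float rounding
could create or destroy ties.  All tie and threshold comparisons go
through the rational path; floats appear only in exports.

Admissible references are those carrying a nominal binomial species label
(`^[A-Z][a-z]+ [a-z][a-z-]+$` after whitespace normalisation).  Records
with provisional labels — morphospecies codes like "Fannia sp1", or
collection codes — are excluded from the reference side but may serve as
queries; for them a separate `genus_correct` flag reports genus-level
agreement, never folded into species-level correctness.  Synonymy
resolution is out of scope: correctness is exact label equality.

An optional `max_hits` cap (99 when emulating the BOLD identification
engine) truncates the candidate list after a deterministic sort
(similarity descending, then reference id ascending).  The real service's
internal ordering among equal hits is unspecified; the deterministic
tie-break makes runs reproducible, which tests require.

### Kimura 2-parameter correction

`k2p` implements d = −½·ln((1 − 2P − Q)·√(1 − 2Q)) with P and Q the
transition (A↔G, C↔T) and transversion proportions over the overlap.  It
is provided because corrected distances are customary in barcoding; the
identification engine itself runs on 1 − p, which the case study verified
to agree with the similarity scores of the public search services at the
small distances that matter (< 1%).  Saturated inputs (log domain
violations) raise rather than returning NaN.

## Haplotype collapsing

Two records share a haplotype when they are identical at every site where
both are unambiguous, so a terminal run of Ns does not create a spurious
new haplotype.  This relation is not transitive (`AAN` matches both `AAT`
and `AAC`); haplotypes are therefore the connected components of the
compatibility graph, computed with networkx.  The behaviour is documented
and unit-tested; a `strict` mode (exact string equality) is available
because the choice is a genuine judgment call and source data vary in how
they treat ambiguity codes.  Haplotype ids are numbered from 1 in order of
first appearance, independently per fragment kind (the ~658 bp barcode and
the ~1.5 kb long COI fragment carry separate numberings, as in the
case-study tables).

## Quality control

`qc_record` checks ungapped length against a minimum (500 bp, the
admission rule of the emulated reference libraries), the IUPAC alphabet,
and open reading frames: a record passes the stop-codon check iff at least
one of the three *forward* frames has no internal stop under the
invertebrate mitochondrial code (translation table 5; stops TAA/TAG, via
Biopython's codon tables).  Barcode submissions are conventionally
oriented 5'→3' on the coding strand, and the reading frame of a fragment
is unknown, so scanning the three forward frames is the weakest test that
still fails a typical nuclear pseudogene (which accumulates frame-breaking
substitutions).  Codons containing ambiguity codes are never called as
stops; the terminal, possibly partial codon is ignored.

## The case-study fixture

`data/diptera_case_study_specimens.tsv` transcribes a published
per-specimen results table: 85 adult flies of 16 species (three *Fannia*
morphospecies counted separately) from Belgium and France, with barcode
and long-fragment haplotype ids and the best-match similarity obtained
under each of four search configurations (`proc12` barcode vs public
records — two services returning identical results; `proc3` barcode vs
species-level records including early releases; `proc4` barcode vs
barcode-tagged records; `proc5` long fragment vs public records).
`data/diptera_case_study_annotations.tsv` carries the per-species outcome
annotations (correct-unambiguous, ambiguous with/without exact tie,
incorrect-only, none), including the incorrect species names involved.

Transcription conventions worth knowing:

* An empty similarity cell means "no best match above 99%"; `na` means the
  fragment was not available for that specimen.
* Six long-fragment cells carry the marker `+`: the per-species summaries
  establish that these haplotypes *did* have best matches above the
  threshold, but the individual printed values are not recoverable from
  the source transcription.  Aggregation only uses presence, so the
  marker is lossless for every computed metric.
* One procedure-4 cell (NICC029-13) prints 98.94 — marginally below the
  nominal threshold — yet the published aggregates count it as a match;
  the loader admits it and the aggregation follows the populated-cell
  rule.
* The long-haplotype column enumerates 62 specimens with the long
  fragment (23 `na` cells); the companion per-species haplotype counts
  are fully consistent with that enumeration.

`summarize_fixture` recomputes every published aggregate from this table:
query universe = distinct haplotypes of the relevant fragment; a
haplotype has matches iff its cell is populated; ambiguity joins the
species annotation onto the haplotypes.  The *restricted* mode evaluates
barcode-fragment results over the 42 long-fragment haplotypes (each
inheriting its specimens' barcode cell, species universe = the 15 species
with a long fragment), which is the universe on which the long-fragment
configuration is judged — this decoding reproduces every bracketed and
parenthesised cell of the published summary table.

### Percent conventions

"With matches" percents divide by all queries (species) in the universe;
unambiguous/ambiguous percents divide by the queries (species) *with*
matches.  This pair of denominators is the only one consistent with every
published cell (e.g. 18/36 = 50%, 25/40 → 62%, 19/26 → 73%).  Rounding is
round-half-even to integer percent — the only common rule consistent with
both printed half-way cases (62.5 → 62 and 37.5 → 38); Python's `round`
on an exact `Fraction` implements it without float detours.

## Synthetic data

`simulate` generates libraries with the structure the classifier relies
on, so every pipeline stage is testable offline:

* **Star phylogeny.**  One random ancestral sequence; each species'
  centroid is the ancestor with *m* substitutions, *m* drawn uniformly so
  that pairwise centroid distances land in the configured band, then
  rejection-checked against the realized pairwise distances.  Only the
  divergence *ranges* matter to threshold identification, so a full
  coalescent would add realism the classifier cannot see.
* **Members.**  The first reference and first query of each species sit
  exactly on the centroid (the modal haplotype); other members carry up
  to `floor(intra_max_p·L/2)` substitutions, bounding realized *pairwise*
  intraspecific distances by `intra_max_p`.
* **Defaults** trace to the case study: `seq_len` 658 bp,
  `intra_max_p` 0.005, `inter_min_p` 0.066, `inter_max_p` 0.162 (the
  observed intraspecific and congeneric p-distance ranges), 10 species ×
  5 references × 2 queries — a library of the same order as one genus'
  representation in the real data.  All species are congeneric, mirroring
  the hard case.
* **Defects.**  `dropout_species` removes species from the library while
  keeping their queries (missing-species failure); `mislabel_rate`
  reassigns labels of `round(rate·n_refs)` random references
  (misidentified-specimen failure); `shared_haplotype_pairs` deposits one
  species' centroid under another's name; and
  `plant_mislabelled_duplicate` puts a foreign-labelled record exactly on
  a centroid, which provably produces an ambiguous identification with an
  exact tie for the centroid query.  A `TruthTable` records everything.
* **Substitutions only, no indels** — COI barcodes of these taxa are
  indel-free and the pipeline assumes positional comparability.  Mutation
  sites are drawn without replacement per record; the substituted base is
  uniform over the three alternatives.

What the simulator does *not* emulate: sequencing error and chimeras,
rate heterogeneity along the gene, codon structure (synthetic sequences
are not translatable), population structure within species, and the
composition biases of real public libraries.  Passing tests on synthetic
data therefore show the *engine* is correct under the stated divergence
geometry; they do not certify any particular real library.

`fixture_structured_library` builds synthetic sequences realizing the
case-study haplotype structure exactly (one distinct sequence per
haplotype id, assigned to specimens per the table), so collapsing
recovers the transcribed partition; `emulated_search_library`
additionally constructs reference sets realizing each procedure's
annotated outcome pattern (identical conspecifics where matches were
found, a congener 3 substitutions off the centroid for ambiguity, an
identical foreign-labelled duplicate per tied haplotype), letting the
live engine reproduce the published aggregates end-to-end rather than by
re-tabulation.

## Numerical and design notes

* Thresholds are expressed in percent on the CLI (99, 99.5) and converted
  to exact rationals internally.
* `threshold_sweep` computes distances once and re-filters per threshold;
  thresholds must be strictly increasing, and `NO_MATCH` counts are
  monotone along the sweep.
* Degenerate inputs: empty query lists yield empty results; a reference
  library that is empty after provisional/source filtering is a
  configuration error; comparisons with fewer than `min_overlap`
  comparable sites are skipped and counted in search diagnostics, and
  raise when requested directly.
* Zero-denominator percents (no queries with matches) are reported as
  `None`, never as 0.
* Problem sizes in tests and the acceptance script (libraries of tens of
  references, 658 bp, 25 random libraries for the oracle cross-check,
  5 seeds for recovery checks) were chosen as the smallest sizes at which
  every behaviour of interest — ties, truncation, dropout fractions —
  is exercised deterministically.

## Known limitations

* No alignment construction: inputs must be pre-aligned (equal length);
  indels are not modelled.
* No synonymy or taxonomic-rank handling beyond the genus flag.
* Only the forward strand is scanned in QC; reverse-complemented input is
  the caller's responsibility.
* The emulation of hit-capped services cannot reproduce their internal
  (unspecified) ordering among equally similar hits, only the cap itself.
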