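# Methods

`foldprep` implements the computational layer that surrounds a protein
structure predictor: building and filtering multiple sequence alignments
(MSAs) from homology-search output, pairing and assembling MSAs for complex
prediction, deriving confidence metrics from predictor output, and
scheduling batches of predictions efficiently. The predictor itself is a
pluggable contract; everything here runs at desk scale on synthetic inputs.

## Alignments and identity arithmetic

All alignments use the A3M convention: uppercase letters and `-` occupy
match columns (one per query residue); lowercase letters are insertions
relative to the query and occupy no column. Conversion from aligned FASTA,
Stockholm and Clustal turns columns that are gaps in the query into
insertions, so every dialect lands in the same in-memory form.

Sequence identity between two rows is the number of columns carrying the
same residue divided by the **query length**, not the alignment length.
This is the semantics under which rows are assigned to identity buckets,
and it makes a short fragment's identity proportional to how much of the
query it explains. `X` (unknown residue) never counts as a match, and
insertions are excluded — they occupy no query column. Coverage uses the
recorded query span `(qstart, qend, qlen)` when the search reported one,
else the fraction of match columns carrying a residue.

For large row sets, all-pairs identities are computed as 20 rank-k updates
(one boolean matrix product per amino-acid symbol), which keeps the
saturated-bucket filter below ~20 s for 25,000 rows of length 50 on one
CPU. Problem sizes throughout the tests and the acceptance script (25,000
MSA rows, 200-member clusters, 20×50 databases) were chosen so each check
completes in seconds while still saturating every code path the filters
branch on.

## The staged diversity filter

MSA construction applies three filter stages:

1. **Per-cluster filter.** When a database hit is expanded to its cluster
   members, each cluster is independently reduced so that no retained pair
   exceeds 95% identity. The filter is a greedy scan in input order: a row
   is kept iff its identity to every already-kept row is at most the
   threshold. Greediness guarantees the output contains no pair above the
   threshold; because it runs per cluster, identical sequences arriving
   from two different clusters both survive.
2. **Score filter (qsc).** Rows must score at least 0.8 per query column
   against the query. The score is the BLOSUM62 (half-bit integer matrix)
   sum over aligned columns, divided by the query length and by a scale
   constant of 4.0. The scale is chosen so that any query's self-score per
   column is ≥ 1.0 (the smallest BLOSUM62 diagonal entry is 4), which makes
   the 0.8 threshold a meaningful "most of a self-match" criterion. Gap and
   insertion columns contribute zero. The filter only activates once 100
   hits are present, so sparse MSAs are never thinned; a threshold of 0 or
   below disables it entirely (stage 3 runs with qsc 0, i.e. off — a
   literal "score ≥ 0" cutoff would empty the low-identity buckets, whose
   rows necessarily score negative).
3. **Bucketed diversity filter.** Non-query rows are assigned to identity
   buckets [0.0–0.2], (0.2–0.4], (0.4–0.6], (0.6–0.8], (0.8–1.0] by query
   identity (first bucket closed, later buckets left-open). Buckets holding
   fewer than 1,000 rows pass through untouched; saturated buckets are
   filtered **within the bucket only** — the 95% maximum-pairwise-identity
   filter first, then farthest-point selection down to the 3,000 most
   diverse rows. Filtering within buckets means redundancy removal among
   close homologs can never eliminate the remote-homolog diversity that
   carries most of the coevolution signal.

Diversity selection is deterministic farthest-point greedy: the first row
in input order seeds the selection, each step adds the row whose minimum
distance (1 − identity) to the selected set is largest, ties broken by
input order, and output preserves input order. Running the identity filter
before the diversity cap (the two are unordered in the production flag
set) keeps a saturated bucket at exactly the cap and makes the whole stage
idempotent.

## MSA construction from hit tables

The iterative profile search itself is out of scope; its output arrives as
a BLAST-tabular-like TSV of hits against cluster representatives (with
aligned strings, cluster ids, taxids and accessions as extra columns), and
a cluster table carrying each member's stored pairwise alignment to its
representative. Hits are accepted at E-value strictly below 0.1. Cluster
members are projected into the query frame by composing the
member↔representative alignment with the representative→query alignment
through the representative's residues — the same information a
profile-based realignment would use, without the profile machinery.
Representative insertions relative to the query are dropped during
composition. Each cluster is expanded at most once per query.

`naive_search` provides a deterministic exhaustive Smith–Waterman backend
(BLOSUM62, gap open −11 / extend −1, Biopython's `PairwiseAligner`) for
desk-scale runs, with E-values from the Karlin–Altschul formula
E = K·m·n·exp(−λS) using the standard gapped-BLOSUM62 constants λ = 0.267,
K = 0.041. Two caveats are documented rather than patched: a correctly
calibrated E-value flags ≈9.5% of random comparisons below 0.1 by
construction (P = 1 − e^(−0.1)); and a query aligned against its own
reversal is not a null comparison, since a local aligner finds genuine
palindromic self-matches.

The two database MSAs (the curated and the environmental set) are filtered
independently and concatenated behind the query; whether joint filtering
would be preferable is an open design point, and independence was chosen
because the two databases sample different sequence spaces.

## Pairing for complexes

Species pairing: hits covering less than 50% of their query are discarded;
a species contributes one paired row iff it then has at least one hit for
every chain, and per chain the smallest-E-value hit is used (ties broken
by target id for determinism). Blocks are ordered by summed E-value. One
block per species — paralog pairs are deliberately not emitted, since
without genome context the orthology of secondary hits is unknown.

Genome-distance pairing (for prokaryotes, where interacting genes cluster
in operons): accessions are mapped to integer ordinals by reading their
alphanumeric characters as one base-36 number, so consecutively issued
accessions get consecutive ordinals. Within a species, two chains are
matched greedily over candidate pairs sorted by ordinal distance; matches
farther than `max_gap` (default 10 ordinals, a heuristic) are rejected.
With more than two chains, the first chain anchors the block and the other
chains match against it. Greedy matching is verified against exhaustive
enumeration on small instances in the tests; it is not guaranteed optimal
in general.

## Feature assembly

Homo-oligomers copy the MSA once per subunit, each copy occupying its own
column block with every other block gap-filled (block-diagonal layout);
rows are emitted copy-major. Hetero-oligomers put the concatenated query
first, then the paired rows (full-width), then each chain's unpaired rows
block-diagonally. Paired rows are not deduplicated against unpaired
blocks.

Chain breaks are encoded through the residue index: indices run
consecutively within a chain and jump by `chain_gap` (default 200) between
chains. The relative-position encoding clips at |i − j| ≥ 32, so any gap
above 32 makes downstream attention treat the segments as separate chains;
gaps at or below the cap are rejected. 200 is comfortably beyond the cap
and matches common practice. Cross-chain pairs always land in the two
extreme bins (0 and 2·cap) whenever the gap exceeds 2·cap.

MSA subsampling keeps the query plus up to 511 uniformly drawn cluster
rows and up to 1,024 of the remainder as extra rows, deterministically per
seed; iterating seeds is how structure diversity is sampled. The
network-side assignment of extra rows to cluster centers serves no purpose
without the network and is omitted. Fixed-size padding right-pads features
to ceil(L·(1 + 0.1)) with gap tokens (residue index padded with −1), so a
compiled shape serves every query that fits inside it.

## Confidence metrics and ranking

pTM = max_i mean_j 1/(1 + (PAE_ij/d0)²) with d0 = 1.24·(max(N, 19) − 15)^⅓
− 1.8; the clamp at N = 19 keeps d0 positive for short chains. ipTM
restricts the inner mean to cross-chain pairs; inter-PAE is the mean PAE
over ordered cross-chain pairs. Single-chain predictions rank by mean
pLDDT, complexes by ipTM when a chain partition exists (pTM otherwise);
sorts are stable so ties keep input order. The pTM functional form is the
upstream model's published definition, adopted as an external formula.

## Batch scheduling

Queries run in ascending length order so the padded compile shapes grow
monotonically. The compile cache is keyed on (network configuration,
padded length, padded row count); without templates all five models share
one configuration (model 5's), with templates models 1–2 share model 1's
and 3–5 share model 3's. A query reuses the smallest cached shape that
fits it, else a compile event fires for a new 10%-padded shape.

Per query, per sample seed, models run in id order with up to
`num_recycles` (default 3) recycles each. After every recycle the
scheduler checks: if the predictor-reported structure change falls below
`recycle_tolerance`, recycling of that model stops; if the confidence
score (mean pLDDT for single chains, the complex ranking metric otherwise)
reaches `stop_at_score`, the query is finished — remaining recycles,
models and samples are skipped. The score check uses the current recycle's
score, not the best so far. The structure-change metric is whatever the
predictor reports; the contract does not fix it. A predictor exception
marks the query failed and the batch continues. The full event log
(compiles, evaluations, stops) makes runs replayable and is what the
determinism and monotone-work tests assert over.

## Database merge and reduction

New sequences are assigned to an existing cluster when they match its
representative at >30% identity with a local alignment covering ≥90% of
their own length (best qualifying hit); the remainder is clustered
greedily, longest sequence first, each joining the first representative it
matches at the thresholds. Every cluster is then reduced to its 10 most
diverse members by the same farthest-point selection as the MSA filter,
seeded at the representative so it is always retained. Assignment and
remainder-clustering together partition the input — no sequence is lost or
duplicated, which the tests assert.

## 2D rendering

The backbone CA trace is projected to 2D after an optional view rotation;
consecutive-residue segments are sorted ascending by mean transformed z
(painter's algorithm, stable for ties) and shaded linearly from 0.5 at the
farthest segment to 1.0 at the nearest (the shade map is a free choice;
linear is the simplest monotone one). Coloring is by residue index,
per-residue metric (e.g. pLDDT), or chain id. The output is plot-ready
segment data; the matplotlib drawing function is thin, untested
convenience. No spline smoothing or ribbon width is applied — the trace is
rendered as a polyline.

## What the synthetic fixtures do and do not show

The fixture generators produce MSAs whose rows mutate the query at exactly
`round((1 − target)·L)` positions chosen without replacement (so identity
targets are exact and tests are not flaky), species/accession hit layouts,
block-structured PAE matrices with optional clipped Gaussian noise, and
scripted mock predictors that replay a (model, recycle) → score table and
raise on any unscripted call. All generators are seed-deterministic.

Rows are independent point-mutation sets: there is no phylogenetic
correlation, no indels in the generated alignments, no composition bias,
and mock predictor scores carry no relationship to any structure. Passing
tests therefore demonstrate the correctness of the filtering, pairing,
assembly, ranking and scheduling *algorithms* under controlled identity
structure — not that any particular biological MSA will yield a good
structure prediction.

## Known limitations

- The naive search backend is quadratic and desk-scale only; k-mer
  prefiltering and profile search are out of scope.
- Genome-distance pairing's anchored matching for >2 chains is a heuristic;
  only the two-chain case is verified against exhaustive matching.
- The qsc score is not bit-exact with HHblits' score-per-column statistic;
  the scale constant makes thresholds comparable, not identical.
- Iteration logic of the profile search is not simulated; hit tables are
  consumed as given, one per database.
- Deletion-count features and template features of real model input are
  not produced; the feature set carries only what downstream modules
  consume.
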