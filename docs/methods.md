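# Methods

## Coordinates and normalization

All coordinates are 1-based inclusive on the forward strand of the respective
sequence, matching the convention of nhmmer's target-hits table. Hit parsers
normalize minus-strand rows (genome coordinates descending in nhmmer tblout,
`sstart > send` in BLAST tabular) so that `target_start <= target_end` always
holds; orientation is carried only by the strand flag, and query coordinates
always refer to the query forward strand. This makes the joining arithmetic
identical on both strands. BED output converts to 0-based half-open on write
and tests assert the round trip is exact.

nhmmer's table carries the *target* sequence length but not the query length,
so query lengths are resolved from the query FASTA catalog at parse time; a
hit referencing a query absent from the catalog is an error rather than a
guess.

## Filtering

A match is kept iff its E-value is at most `evalue_max` (default `1e-5`,
boundary inclusive: a hit "meeting" a threshold includes equality) and its
length on the genome is at least `min_match_length` (default 0 nt; a survey
of short, repeat-rich phages such as Pf typically raises this — the bundled
case-study configuration uses 1,000 nt). Filtering is order-preserving, pure
and idempotent; both properties are tested.

## Fragment joining

Matches are first grouped by (genome sequence, query phage, strand). Grouping
before scanning means a hit to a *different* phage lying between two
fragments cannot break their chain; since criterion A forbids cross-query
joins anyway, this changes no join decision, and it keeps tandem or nested
integrations of different phages individually resolvable. Within a group,
matches sorted by (genome start, genome end, query start) are scanned left to
right; a match extends the current chain iff it is joinable with the chain's
*last* fragment, else it starts a new chain.

Joinability of a consecutive pair (prev before next on the genome):

* same query, genome and strand (a single integration event cannot produce
  opposite-strand colinear fragments);
* colinearity: on `+`, the next fragment's query interval must not start or
  end before the previous one's; on `-` the mirrored condition;
* genome gap: `|i - j| <= n * k` with `i` = prev's genome end, `j` = next's
  genome start, `n` the query length, `k = 0.25` by default. The bound is
  inclusive and scales with the query so that a fixed relative insertion
  tolerance applies to phages of any size;
* query overlap at most `theta = 50` nt (inclusive). The overlap is computed
  between the adjacent query boundaries in genome order (`prev.query_end` /
  `next.query_start` on `+`, `prev.query_start` / `next.query_end` on `-`).
  A non-positive overlap is a query gap and passes unconditionally: deletions
  in the integrated copy, however large, are never a reason to split an
  integration, whereas large duplicated query stretches indicate two
  independent copies.

Integration IDs are deterministic — `<genome_id>_<ordinal>` with ordinals
assigned along the genome — so identical inputs give byte-identical outputs.
No cap is placed on fragments per chain.

The greedy scan links only sort-adjacent group members, so its partition
equals the connected components of the "adjacent-and-joinable" graph; the
test suite checks this equivalence against an independent
connected-components oracle (networkx) on 1,000 random instances, along with
the partition property (every filtered match in exactly one integration) and
monotonicity (loosening `k` or `theta` never increases the integration
count).

## Full-length calls and coverage

Query coverage of an integration is the length of the union of its fragments'
query intervals — overlap between fragments is counted once, and a
multi-fragment integration is assessed as the single event it represents. An
integration is full length iff coverage ≥ `full_length_fraction * n`
(default 0.70, inclusive). Raising the fraction can only turn True flags
False, never the reverse (tested).

## Occurrence profiles and summaries

Per query phage, the profile counts at each position the number of
integrations in the dataset whose coverage includes that position. The
counting unit is the integration (union over its fragments), not the
fragment: fragment-level counting would double-count positions where
fragments of one joined integration overlap. After every build the
conservation identity `sum(counts) == sum of contributing integrations'
coverage` is asserted. The JSON run summary (genome-level integration
records, query-level counts and per-integration query extents) is validated
against pydantic models on write; `docs/summary.schema.json` is the JSON
Schema generated from those models and carries a `schema_version` field.

The annotation TSV reports one row per fragment, fragments of one
integration sharing the integration ID and full-length flag, with a fixed
column order and `True`/`False` literals; write→read is the identity on all
serialized fields (E-values are written with full precision and parsed with
round-trip float parsing). The TSV does not carry query lengths, so records
read back have unknown query length and their full-length flag is taken from
the file rather than recomputed.

## The synthetic-data generator

The simulator emulates the pipeline's study conditions: i.i.d. background
sequence at a configurable GC fraction (default 0.60, typical of
*Pseudomonas*), and planted phage copies in three modes — full copy,
truncated contiguous slice (fraction drawn from 0.30–0.90), or a copy split
in two with a random spacer between the pieces. The spacer length is
expressed as a fraction of the query length (default 0.10, inside the
default joining bound `k = 0.25`; raising it above 0.25 deliberately
violates the genome-gap criterion for negative controls), and the split
point can overlap or gap on the query to exercise the overlap cap.
Minus-strand plantings insert the reverse complement. Default query length
is 10,000 nt (the scale of filamentous Inovirus genomes) and plantings are
inserted — never overwritten — into the background.

Mutations are point substitutions only (each base independently replaced by
a uniformly chosen different base), so ground-truth coordinates remain exact
without alignment; indel tolerance of the joining step is exercised by the
fragmented mode instead. Insertion sites are kept at least
`min_separation_fraction` × query length apart (default 0.35, above
`k = 0.25`) so that two independent plantings of the same phage can never
legitimately satisfy the joining criteria — without this margin,
single-event ground truth would be ill-posed. All randomness flows through
one integer seed; query, background and planting draws use decorrelated
streams derived from it, and identical configurations produce byte-identical
FASTA and truth files.

What the simulator does **not** model: phage gene content and selection,
recombination, indels within homologous segments, compositional bias of real
integration sites (att sites), or sequencing error. Passing recovery tests
therefore demonstrate the correctness of the filtering/joining/calling logic
under known ground truth, not detection sensitivity on real diverged
prophages — for that, the pipeline consumes real nhmmer/BLAST output.

## The naive built-in detector

`naive_detect` is an exact-k-mer seed (default k = 15) and ungapped x-drop
extension (default x = 20, +1 match / −1 mismatch, N never matches) search,
trimmed to the maximum-scoring extent, with same-diagonal overlapping hits
merged. It exists so the full pipeline runs offline; it is not a replacement
for a calibrated search tool. Its hits carry E-value 0 — no statistics are
implemented — so when it feeds the pipeline, significance filtering falls to
the match-length filter; tests use 100 nt, roughly an order of magnitude
above chance seed hits (15–50 nt, e.g. from k-mer self-repeats of a query)
and below the shortest planted piece (≥ 1,500 nt at the simulated sizes).
Reported boundaries can deviate from the planted truth by up to k − 1 = 14 nt
(a seed cannot anchor the last mismatched bases of a flank) and extension may
overrun into chance-matching flank by at most the x-drop width; recovery
tests assert within these widths.

Test problem sizes — 20–60 kb genomes, 3–10 kb queries, 25–50 replicates —
were chosen so the pure-Python detector completes a replicate in well under a
second while leaving every joining scenario (fragmentation, truncation,
strand, mutation at 5%) represented.

## Command-line workflow

`annotate` resolves thresholds with precedence flags > config file >
defaults, echoes the resolved configuration into a run manifest, and
processes genomes independently (outputs are a pure function of each
genome's inputs, so processing order and parallelization cannot change
results). `simulate` writes genome/query FASTA plus the truth table;
`check` reports, per planting, whether exactly one reported integration of
the same genome/query/strand overlaps the truth span ("recovered single"),
the larger of the two boundary deviations, and full-length agreement, with
summary rates. Logging goes to standard error; all outputs are deterministic
given the seed, manifest timestamps aside.

## Known limitations

* The greedy scan extends a chain only from its last fragment; a pathological
  arrangement in which a match is joinable with an earlier but not the latest
  fragment of a chain starts a new integration. This mirrors the
  "consecutive matches" definition of the joining step and keeps the
  procedure deterministic.
* No combined significance is computed for a joined integration; per-match
  E-values are reported as-is.
* `att`-site detection, gene-level annotation of phage/bacterial genomes and
  HTML visualization are outside this package's scope; the JSON summary
  exposes the data a visualization layer needs.
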