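# prophagekit

Annotate prophage integrations in bacterial genomes from DNA homology hits —
including integrations that homology search reports in pieces.

Temperate phages integrate into bacterial chromosomes and persist there as
prophages. When a diverged prophage is searched for with a query phage
sequence (e.g. with `nhmmer` or `blastn`), a single integration is frequently
reported as several alignment fragments lying near each other on the genome,
particularly when the integrated copy carries a large insertion or deletion
relative to the query. Counting those fragments as separate prophages
inflates integration counts and hides full-length elements. `prophagekit`
implements the post-processing that fixes this, plus everything needed to
exercise it end to end without external search tools.

## The model

A *match* is one homology hit of a query phage (length *n*) against a genome,
with 1-based inclusive coordinates on the forward strands of both sequences
and a strand flag. After discarding matches with E-value above a cutoff
(default `1e-5`) and, optionally, matches shorter than a minimum length on
the genome, consecutive matches are chained into one *integration* when all
four criteria hold:

* **A** — same query phage, same genome sequence, same strand;
* **B** — colinear: the fragments appear in the same order on the query as on
  the genome (mirrored on the minus strand);
* **Ca** — near on the genome: with *i* the previous fragment's genome end and
  *j* the next fragment's genome start, |*i* − *j*| ≤ *n*·*k*, with gap
  fraction *k* = 0.25 by default;
* **Cb** — minimal overlap on the query: with *s*, *t* the adjacent query
  boundaries in genome order, an overlap (*s* ≥ *t*) may be at most
  θ = 50 nt. Query *gaps* of any size pass — they may be large deletions in
  the integrated copy.

Each chain receives one integration ID. An integration is called **full
length** when the union of its fragments' query intervals covers at least 70%
of the query (configurable). Per query phage, a *position-occurrence profile*
counts, at every query position, how many integrations in the dataset cover
that position — highlighting the parts of a phage that integrate most often.

A substitution-only genome simulator (full, truncated, and spacer-split
plantings on either strand, with ground truth) and a naive exact-seed /
x-drop-extension detector make the entire pipeline runnable and testable
offline; precomputed `nhmmer` tblout or BLAST 12-column tables are consumed
directly when available.

## Worked example

```sh
prophagekit simulate --out sim --seed 42 --genome-length 50000 \
    --query-length 8000 --n-integrations 3 --n-queries 2
prophagekit annotate sim/genome.fasta --phages sim/queries.fasta \
    --min-length 100 --out run
prophagekit check run/genome.annotation.tsv sim/truth.tsv
```

which prints

```
simulated 1 genome with 3 planted integration(s)
annotated 1 genome(s): 3 integration(s), 2 full length
pt001	phage01	single	ids=genome_1 boundary_error=0nt full_length_agrees=True
pt002	phage01	single	ids=genome_2 boundary_error=0nt full_length_agrees=True
pt003	phage01	single	ids=genome_3 boundary_error=2nt full_length_agrees=True
recovery_rate	1.000
full_length_agreement	1.000
```

and `run/genome.annotation.tsv` contains one row per match fragment:

```
phage_name	evalue	score	query_start	query_end	target_name	target_start	target_end	strand	integration_id	full_length
phage01	0.0	5747.0	1745	7491	genome	737	6483	+	genome_1	True
phage01	0.0	2702.0	1	2702	genome	33117	35818	+	genome_2	True
phage01	0.0	5299.0	2702	8000	genome	36618	41916	+	genome_2	True
phage01	0.0	2422.0	964	3385	genome	61179	63600	+	genome_3	False
```

`genome_2` is a composite integration: the planted copy was split by an
800-nt spacer, so the detector reports two fragments, and the joining step —
genome gap 800 ≤ 0.25 × 8000, query overlap 1 nt ≤ 50 — reassembles them
under one ID, covering the query end to end (`full_length` True). `genome_1`
is a truncated copy whose 5,747-nt coverage still clears the 70% bar;
`genome_3` covers only 30% of the query and is reported as partial. The run
directory also holds a BED6 file per genome and `summary.json` with the
integration records and per-query occurrence profiles (schema in
`docs/summary.schema.json`).

`--hits-format nhmmer --hits hits.tbl` (or `blast`) annotates from
precomputed search output instead of the built-in detector.

## Library surface

`prophagekit.matchio` (FASTA, nhmmer/BLAST tables, annotation TSV),
`prophagekit.defrag` (filtering, joining, full-length calls),
`prophagekit.profile` (occurrence profiles, JSON summary, BED),
`prophagekit.simulate` (genome simulator, naive detector, truth tables),
`prophagekit.cli` (the `prophagekit` command). See `docs/methods.md` for the
modelling decisions and their rationale.
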