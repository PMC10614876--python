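"""Synthetic genomes with planted prophage integrations, plus a naive detector.

The generator emulates the inputs of a prophage-annotation run: random
bacterial background sequence with a configurable GC content, and planted
copies of query phages that are full length, truncated, or split in two by a
background "spacer" (mimicking an insertion into the integrated copy).
Plantings can go on either strand (minus-strand copies are inserted as
reverse complements) and can carry point substitutions. Every planting is
recorded in a ground-truth table whose coordinates refer to the final genome.

The mutation model is substitution-only, so truth coordinates stay exact
without any alignment step; indel tolerance of the joining criteria is
exercised by the fragmented mode instead.

``naive_detect`` is a deliberately simple exact-seed / ungapped-x-drop
extension search. It lets the whole pipeline run offline in tests; it carries
no E-value statistics (hits get E-value 0, which passes the downstream
filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import Match, PlantedTruth, SequenceCatalog, SimConfig

PathLike = Union[str, Path]

_BASES = "ACGT"
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")

TRUTH_COLUMNS = [
    "truth_id",
    "query",
    "target",
    "strand",
    "genome_start",
    "genome_end",
    "query_start",
    "query_end",
    "expected_full_length",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_background(
    length: int, gc_fraction: float, seed: Union[int, np.random.Generator]
) -> str:
    """I.i.d. random DNA with P(G) = P(C) = gc_fraction / 2."""
    if length == 0:
        return ""
    rng = _as_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[i] for i in idx)


def mutate(seq: str, rate: float, seed: Union[int, np.random.Generator]) -> str:
    """Point-substitute each base independently with probability ``rate``.

    A mutated base is replaced by a uniformly chosen *different* base, so at
    rate 1 the Hamming distance equals the sequence length.
    """
    if rate == 0 or not seq:
        return seq
    rng = _as_rng(seed)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits) == 0:
        return seq
    out = list(seq)
    for i in hits:
        base = out[i]
        alternatives = [b for b in _BASES if b != base]
        out[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


@dataclass
class _Cassette:
    """One insert to splice into the background, with its query provenance."""

    query_id: str
    strand: str
    sequence: str
    # genome-order list of (offset within cassette, length, query interval)
    parts: list[tuple[int, int, tuple[int, int]]]
    expected_full_length: bool


def _make_cassette(
    query_id: str,
    residues: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    full_length_fraction: float,
) -> _Cassette:
    n = len(residues)
    mode = ["full", "truncated", "fragmented"][
        int(rng.choice(3, p=[cfg.p_full, cfg.p_truncated, cfg.p_fragmented]))
    ]
    strand = "-" if rng.random() < cfg.minus_strand_prob else "+"

    if mode == "full":
        query_pieces = [(1, n)]
    elif mode == "truncated":
        frac = rng.uniform(cfg.truncation_min, cfg.truncation_max)
        length = max(1, int(round(frac * n)))
        start = int(rng.integers(1, n - length + 2))
        query_pieces = [(start, start + length - 1)]
    else:  # fragmented: split with an overlap (>0) or gap (<0) at the breakpoint
        cut = int(rng.integers(int(round(0.3 * n)), int(round(0.7 * n)) + 1))
        b_start = min(n, max(1, cut + 1 - cfg.split_overlap_nt))
        query_pieces = [(1, cut), (b_start, n)]

    piece_seqs = [
        mutate(residues[qs - 1 : qe], cfg.substitution_rate, rng)
        for qs, qe in query_pieces
    ]
    spacer = ""
    if mode == "fragmented":
        spacer = generate_background(int(round(cfg.spacer_fraction * n)), cfg.gc_fraction, rng)

    if strand == "-":
        # genome order reverses query order; each piece is reverse-complemented
        genome_order = list(zip(query_pieces, piece_seqs))[::-1]
        genome_order = [(qi, reverse_complement(s)) for qi, s in genome_order]
    else:
        genome_order = list(zip(query_pieces, piece_seqs))

    sequence = ""
    parts: list[tuple[int, int, tuple[int, int]]] = []
    for k, (q_interval, s) in enumerate(genome_order):
        if k > 0:
            sequence += spacer
        parts.append((len(sequence), len(s), q_interval))
        sequence += s

    covered = sorted(query_pieces)
    total, cur_s, cur_e = 0, covered[0][0], covered[0][1]
    for s0, e0 in covered[1:]:
        if s0 > cur_e + 1:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s0, e0
        else:
            cur_e = max(cur_e, e0)
    total += cur_e - cur_s + 1

    return _Cassette(
        query_id=query_id,
        strand=strand,
        sequence=sequence,
        parts=parts,
        expected_full_length=total >= full_length_fraction * n,
    )


def plant_integrations(
    background: str,
    queries: SequenceCatalog,
    simconfig: SimConfig,
    full_length_fraction: float = 0.70,
) -> tuple[str, list[PlantedTruth]]:
    """Insert ``n_integrations`` phage copies into the background.

    Inserts never overwrite background sequence. Insertion sites are kept at
    least ``min_separation_fraction`` x query length apart so that distinct
    planted events stay farther apart than the default joining gap and
    remain individually resolvable. Returns the final genome and one
    :class:`PlantedTruth` per planting, coordinates on the final genome.
    """
    rng = _as_rng(simconfig.seed)
    query_ids = sorted(queries)
    if simconfig.n_integrations == 0:
        return background, []
    if not query_ids:
        raise ValueError("no query sequences to plant")

    cassettes = []
    for _ in range(simconfig.n_integrations):
        qid = query_ids[int(rng.integers(len(query_ids)))]
        cassettes.append(
            _make_cassette(qid, queries.residues_of(qid), simconfig, rng, full_length_fraction)
        )

    total_planted = sum(len(c.sequence) for c in cassettes)
    max_qlen = max(queries.length_of(q) for q in query_ids)
    min_sep = int(math.ceil(simconfig.min_separation_fraction * max_qlen))
    slack = len(background) - (simconfig.n_integrations - 1) * min_sep
    if len(background) <= total_planted or slack <= 0:
        raise ValueError(
            f"insufficient background length {len(background)} for "
            f"{simconfig.n_integrations} planting(s) totalling {total_planted} nt"
        )
    raw = np.sort(rng.integers(0, slack + 1, size=simconfig.n_integrations))
    loci = [int(raw[i]) + i * min_sep for i in range(simconfig.n_integrations)]

    genome_parts: list[str] = []
    truths: list[PlantedTruth] = []
    prev = 0
    inserted = 0
    for i, (locus, cassette) in enumerate(zip(loci, cassettes)):
        genome_parts.append(background[prev:locus])
        prev = locus
        cassette_start = locus + inserted + 1  # 1-based start in final genome
        pieces = [
            ((cassette_start + off, cassette_start + off + length - 1), q_interval)
            for off, length, q_interval in cassette.parts
        ]
        truths.append(
            PlantedTruth(
                truth_id=f"pt{i + 1:03d}",
                query_id=cassette.query_id,
                target_id="genome",
                strand=cassette.strand,
                pieces=pieces,
                substitution_rate=simconfig.substitution_rate,
                expected_full_length=cassette.expected_full_length,
            )
        )
        genome_parts.append(cassette.sequence)
        inserted += len(cassette.sequence)
    genome_parts.append(background[prev:])
    return "".join(genome_parts), truths


# ---------------------------------------------------------------------------
# naive exact-seed detector
# ---------------------------------------------------------------------------

def _score_region(a: str, b: str) -> int:
    """Match-minus-mismatch count; N never matches."""
    return sum(1 if (x == y and x != "N") else -1 for x, y in zip(a, b))


def _extend_seed(
    gseq: str, qseq: str, gpos: int, qpos: int, k: int, xdrop: int
) -> tuple[int, int, int, int]:
    """Ungapped x-drop extension of an exact k-mer seed (0-based coords).

    Returns the maximum-scoring extent (g0, g1, q0, q1), inclusive.
    """
    # rightward from the seed end
    g_end, q_end = gpos + k - 1, qpos + k - 1
    score, best, best_right = k, k, g_end
    i = 1
    while g_end + i < len(gseq) and q_end + i < len(qseq):
        a, b = gseq[g_end + i], qseq[q_end + i]
        score += 1 if (a == b and a != "N") else -1
        if score > best:
            best, best_right = score, g_end + i
        elif best - score > xdrop:
            break
        i += 1
    # leftward from the seed start
    score, best, best_left = 0, 0, gpos
    i = 1
    while gpos - i >= 0 and qpos - i >= 0:
        a, b = gseq[gpos - i], qseq[qpos - i]
        score += 1 if (a == b and a != "N") else -1
        if score > best:
            best, best_left = score, gpos - i
        elif best - score > xdrop:
            break
        i += 1
    g0, g1 = best_left, best_right
    return g0, g1, qpos - (gpos - g0), q_end + (g1 - (gpos + k - 1))


def naive_detect(
    genome: Union[str, SequenceCatalog],
    queries: SequenceCatalog,
    seed_kmer: int = 15,
    xdrop: int = 20,
    target_id: str = "genome",
) -> list[Match]:
    """Exact-seed + ungapped-extension homology search.

    Every ``seed_kmer``-mer shared between a query (either strand) and the
    genome seeds an ungapped extension scored +1 per match / -1 per mismatch,
    stopped when the running score drops ``xdrop`` below its maximum and
    trimmed to the maximum-scoring extent. Hits on one (query, strand)
    diagonal with overlapping extents are merged. Emitted matches carry
    ``score`` = match-minus-mismatch count over the final extent and
    ``evalue`` = 0 (no statistical calibration; the downstream E-value filter
    passes them through).
    """
    if seed_kmer < 4:
        raise ValueError("seed_kmer must be >= 4")
    if isinstance(genome, SequenceCatalog):
        out: list[Match] = []
        for gid in sorted(genome):
            out.extend(
                naive_detect(genome.residues_of(gid), queries, seed_kmer, xdrop, target_id=gid)
            )
        return out

    k = seed_kmer
    # one index over all queries and both strands: k-mer -> [(qid, strand, qpos)]
    index: dict[str, list[tuple[str, str, int]]] = {}
    oriented: dict[tuple[str, str], str] = {}
    for qid in sorted(queries):
        q = queries.residues_of(qid)
        for strand in "+-":
            s = q if strand == "+" else reverse_complement(q)
            oriented[(qid, strand)] = s
            for p in range(len(s) - k + 1):
                kmer = s[p : p + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((qid, strand, p))

    seeds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in range(len(genome) - k + 1):
        hits = index.get(genome[g : g + k])
        if hits:
            for qid, strand, qpos in hits:
                seeds.setdefault((qid, strand), []).append((g - qpos, g))

    matches: list[Match] = []
    for (qid, strand), seed_list in sorted(seeds.items()):
        qseq = oriented[(qid, strand)]
        n = len(qseq)
        seed_list.sort()
        extents: dict[int, list[tuple[int, int]]] = {}
        covered_end: dict[int, int] = {}
        for diag, g in seed_list:
            if g <= covered_end.get(diag, -1):
                continue
            g0, g1, _q0, _q1 = _extend_seed(genome, qseq, g, g - diag, k, xdrop)
            covered_end[diag] = g1
            extents.setdefault(diag, []).append((g0, g1))

        for diag, spans in sorted(extents.items()):
            spans.sort()
            merged = [list(spans[0])]
            for g0, g1 in spans[1:]:
                if g0 <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], g1)
                else:
                    merged.append([g0, g1])
            for g0, g1 in merged:
                q0, q1 = g0 - diag, g1 - diag
                score = _score_region(genome[g0 : g1 + 1], qseq[q0 : q1 + 1])
                if strand == "+":
                    query_start, query_end = q0 + 1, q1 + 1
                else:
                    query_start, query_end = n - q1, n - q0
                matches.append(
                    Match(
                        query_id=qid,
                        target_id=target_id,
                        query_start=query_start,
                        query_end=query_end,
                        target_start=g0 + 1,
                        target_end=g1 + 1,
                        strand=strand,
                        evalue=0.0,
                        score=float(score),
                        query_length=n,
                        source="naive",
                    )
                )
    matches.sort(key=lambda m: (m.target_id, m.target_start, m.target_end, m.query_id))
    return matches


# ---------------------------------------------------------------------------
# truth-table I/O and dataset convenience
# ---------------------------------------------------------------------------

def write_truth_tsv(truths: list[PlantedTruth], path: PathLike) -> None:
    """One row per truth piece; pieces of one planting share truth_id."""
    rows = []
    for t in truths:
        for (gs, ge), (qs, qe) in t.pieces:
            rows.append(
                {
                    "truth_id": t.truth_id,
                    "query": t.query_id,
                    "target": t.target_id,
                    "strand": t.strand,
                    "genome_start": gs,
                    "genome_end": ge,
                    "query_start": qs,
                    "query_end": qe,
                    "expected_full_length": bool(t.expected_full_length),
                }
            )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: PathLike) -> list[PlantedTruth]:
    """Inverse of :func:`write_truth_tsv` on the serialized columns.

    The substitution rate is not part of the table; read-back records carry
    rate 0.0.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"expected_full_length": str})
    truths: list[PlantedTruth] = []
    for truth_id, rows in frame.groupby("truth_id", sort=False):
        rows = rows.sort_values("genome_start")
        first = rows.iloc[0]
        truths.append(
            PlantedTruth(
                truth_id=str(truth_id),
                query_id=str(first["query"]),
                target_id=str(first["target"]),
                strand=str(first["strand"]),
                pieces=[
                    (
                        (int(r["genome_start"]), int(r["genome_end"])),
                        (int(r["query_start"]), int(r["query_end"])),
                    )
                    for _, r in rows.iterrows()
                ],
                substitution_rate=0.0,
                expected_full_length=str(first["expected_full_length"]) == "True",
            )
        )
    return truths


def simulate_dataset(
    simconfig: SimConfig,
) -> tuple[SequenceCatalog, SequenceCatalog, list[PlantedTruth]]:
    """Generate query phages, a background genome, and plant integrations.

    Queries are random sequences (ids ``phage01`` ...) of
    ``simconfig.query_length`` nt at the configured GC content. Everything is
    driven by ``simconfig.seed``; identical configs give identical output.
    """
    # queries and background draw from streams decorrelated from the planting
    # stream (which plant_integrations derives from the bare seed), so a spacer
    # can never replay the draws that produced a query
    queries_rng = np.random.default_rng([1, simconfig.seed])
    background_rng = np.random.default_rng([2, simconfig.seed])
    queries = SequenceCatalog()
    for i in range(simconfig.n_queries):
        qid = f"phage{i + 1:02d}"
        queries.add(
            qid,
            simconfig.query_length,
            generate_background(simconfig.query_length, simconfig.gc_fraction, queries_rng),
        )
    background = generate_background(
        simconfig.genome_length, simconfig.gc_fraction, background_rng
    )
    genome, truths = plant_integrations(background, queries, simconfig)
    genome_catalog = SequenceCatalog()
    genome_catalog.add("genome", len(genome), genome)
    return genome_catalog, queries, truths


# ---------------------------------------------------------------------------
# recovery evaluation against planted truth
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    rows: list[dict] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        if not self.rows:
            return 0.0
        return sum(r["recovered_single"] for r in self.rows) / len(self.rows)

    @property
    def full_length_agreement_rate(self) -> Optional[float]:
        hit = [r for r in self.rows if r["recovered_single"]]
        if not hit:
            return None
        return sum(r["full_length_agrees"] for r in hit) / len(hit)


def evaluate_recovery(integrations, truths: list[PlantedTruth]) -> RecoveryReport:
    """Score annotation output against planted truth.

    A planting is *recovered single* iff exactly one reported integration
    with the same target, query and strand overlaps its genome span; the
    boundary error is then the larger end deviation in nt.
    """
    report = RecoveryReport()
    for t in truths:
        ts, te = t.genome_span
        candidates = [
            integ
            for integ in integrations
            if integ.target_id == t.target_id
            and integ.query_id == t.query_id
            and integ.strand == t.strand
            and integ.genome_span[0] <= te
            and integ.genome_span[1] >= ts
        ]
        row = {
            "truth_id": t.truth_id,
            "query": t.query_id,
            "n_observed": len(candidates),
            "observed_ids": [c.integration_id for c in candidates],
            "recovered_single": len(candidates) == 1,
            "boundary_error_nt": None,
            "full_length_agrees": False,
        }
        if len(candidates) == 1:
            (ps, pe) = candidates[0].genome_span
            row["boundary_error_nt"] = max(abs(ps - ts), abs(pe - te))
            row["full_length_agrees"] = candidates[0].full_length == t.expected_full_length
        report.rows.append(row)
    return report
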