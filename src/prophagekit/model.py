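"""Core data model shared by the I/O, joining, profiling and simulation layers.

Coordinate convention: all coordinates, in memory and on disk, are 1-based
inclusive on the forward strand of the respective sequence (the convention of
nhmmer's target-hits table). Minus-strand hits are normalized at parse time so
that ``target_start <= target_end`` always holds and orientation lives solely
in the ``strand`` flag; query coordinates always refer to the query forward
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Match",
    "SeqEntry",
    "SequenceCatalog",
    "PipelineConfig",
    "Integration",
    "OccurrenceProfile",
    "PlantedTruth",
    "SimConfig",
    "normalize_strand",
]

_MINUS_ALIASES = {"-", "−", "minus"}  # ASCII hyphen, Unicode minus


def normalize_strand(value: str) -> str:
    """Map strand spellings (including the Unicode minus sign) to '+' or '-'."""
    v = str(value).strip()
    if v == "+" or v == "plus":
        return "+"
    if v in _MINUS_ALIASES:
        return "-"
    raise ValueError(f"invalid strand {value!r}")


@dataclass
class Match:
    """One homology hit between a query phage and a target genome.

    ``query_length`` is the full length of the query phage (the *n* of the
    genome-gap joining criterion); it may be None for matches read back from
    an annotation TSV, which does not record it.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    evalue: float
    score: float
    query_length: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.strand = normalize_strand(self.strand)
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for match to {self.query_id}")
        if not (1 <= self.query_start <= self.query_end):
            raise ValueError(
                f"invalid query interval {self.query_start}..{self.query_end} on {self.query_id}"
            )
        if self.query_length is not None and self.query_end > self.query_length:
            raise ValueError(
                f"query interval end {self.query_end} exceeds query length "
                f"{self.query_length} on {self.query_id}"
            )
        if not (1 <= self.target_start <= self.target_end):
            raise ValueError(
                f"invalid target interval {self.target_start}..{self.target_end} on {self.target_id}"
            )

    @property
    def target_span_nt(self) -> int:
        """Length of the match on the target genome, in nucleotides."""
        return self.target_end - self.target_start + 1

    @property
    def query_span_nt(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass
class SeqEntry:
    length: int
    residues: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.residues is not None and len(self.residues) != self.length:
            raise ValueError("residue count does not equal declared length")


@dataclass
class SequenceCatalog:
    """Mapping of sequence id -> length (+ optional residues)."""

    entries: dict[str, SeqEntry] = field(default_factory=dict)

    def add(self, seq_id: str, length: int, residues: Optional[str] = None) -> None:
        if seq_id in self.entries:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        self.entries[seq_id] = SeqEntry(length=length, residues=residues)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def length_of(self, seq_id: str) -> int:
        try:
            return self.entries[seq_id].length
        except KeyError:
            raise KeyError(f"unknown sequence id {seq_id!r}") from None

    def residues_of(self, seq_id: str) -> str:
        entry = self.entries.get(seq_id)
        if entry is None:
            raise KeyError(f"unknown sequence id {seq_id!r}")
        if entry.residues is None:
            raise ValueError(f"no residues stored for {seq_id!r}")
        return entry.residues


@dataclass
class PipelineConfig:
    """All thresholds of the annotation workflow.

    evalue_max:
        Matches with E-value above this are discarded (default 1e-5).
    gap_fraction_k:
        Two consecutive fragments may be joined only if their separation on
        the bacterial genome is at most ``gap_fraction_k`` times the query
        phage length (default 0.25).
    max_query_overlap_theta:
        Cap, in nt, on how much consecutive fragments may overlap on the
        query phage (default 50). Query *gaps* are never penalized — they may
        represent large deletions in the integrated copy.
    full_length_fraction:
        An integration covering at least this fraction of its query phage is
        called full length (default 0.70).
    min_match_length:
        Matches shorter than this on the target genome are discarded before
        joining (default 0; the Pseudomonas/Pf case study used 1,000).
    """

    evalue_max: float = 1e-5
    gap_fraction_k: float = 0.25
    max_query_overlap_theta: int = 50
    full_length_fraction: float = 0.70
    min_match_length: int = 0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.gap_fraction_k <= 0:
            raise ValueError("gap_fraction_k must be > 0")
        if self.max_query_overlap_theta < 0:
            raise ValueError("max_query_overlap_theta must be >= 0")
        if not (0 < self.full_length_fraction <= 1):
            raise ValueError("full_length_fraction must be in (0, 1]")
        if self.min_match_length < 0:
            raise ValueError("min_match_length must be >= 0")


@dataclass
class Integration:
    """An ordered chain of matches treated as one prophage integration event."""

    integration_id: str
    query_id: str
    target_id: str
    strand: str
    fragments: list[Match]
    query_coverage_nt: int
    full_length: bool
    query_length: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("integration must contain at least one fragment")
        self.strand = normalize_strand(self.strand)
        self.fragments = sorted(
            self.fragments, key=lambda m: (m.target_start, m.target_end, m.query_start)
        )
        for frag in self.fragments:
            if (frag.query_id, frag.target_id, frag.strand) != (
                self.query_id,
                self.target_id,
                self.strand,
            ):
                raise ValueError(
                    f"fragment {frag.query_id}/{frag.target_id}/{frag.strand} does not "
                    f"belong to integration {self.integration_id}"
                )

    @property
    def genome_span(self) -> tuple[int, int]:
        return (
            min(m.target_start for m in self.fragments),
            max(m.target_end for m in self.fragments),
        )

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class OccurrenceProfile:
    """Per-position integration counts along one query phage.

    ``counts[p-1]`` is the number of integrations whose query coverage
    includes 1-based position ``p``; each integration contributes at most one
    count per position (its fragments' query intervals are unioned first).
    """

    query_id: str
    length: int
    counts: "list[int]"

    def __post_init__(self) -> None:
        if len(self.counts) != self.length:
            raise ValueError("counts vector length must equal query length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth for one planted integration.

    ``pieces`` lists, in genome order, (genome interval, source query
    interval) pairs, both 1-based inclusive on forward strands. Piece lengths
    are equal on genome and query: the mutation model is substitution-only.
    """

    truth_id: str
    query_id: str
    target_id: str
    strand: str
    pieces: list[tuple[tuple[int, int], tuple[int, int]]]
    substitution_rate: float
    expected_full_length: bool

    def __post_init__(self) -> None:
        self.strand = normalize_strand(self.strand)
        prev_end = 0
        for (gs, ge), (qs, qe) in self.pieces:
            if ge - gs != qe - qs:
                raise ValueError(f"{self.truth_id}: piece lengths differ on genome and query")
            if gs <= prev_end:
                raise ValueError(f"{self.truth_id}: genome pieces overlap or are unordered")
            prev_end = ge

    @property
    def genome_span(self) -> tuple[int, int]:
        return (self.pieces[0][0][0], self.pieces[-1][0][1])


@dataclass
class SimConfig:
    """Parameters of the synthetic-genome generator.

    Mode probabilities select, per planting, a full copy, a truncated
    contiguous slice, or a copy split in two by a background spacer. The
    spacer length is expressed as a fraction of the query length so tests can
    place it on either side of the genome-gap joining bound k; the split
    overlap/gap (nt, negative = gap) exercises the query-overlap bound.
    """

    genome_length: int = 100_000
    gc_fraction: float = 0.60
    n_integrations: int = 3
    p_full: float = 0.4
    p_truncated: float = 0.3
    p_fragmented: float = 0.3
    truncation_min: float = 0.30
    truncation_max: float = 0.90
    spacer_fraction: float = 0.10
    split_overlap_nt: int = 0
    substitution_rate: float = 0.0
    minus_strand_prob: float = 0.5
    min_separation_fraction: float = 0.35
    n_queries: int = 2
    query_length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_full + self.p_truncated + self.p_fragmented
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mode probabilities must sum to 1")
        if not (0 <= self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in [0, 1]")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        if not (0 < self.truncation_min <= self.truncation_max <= 1):
            raise ValueError("truncation range must satisfy 0 < min <= max <= 1")
        if self.genome_length < 0 or self.n_integrations < 0:
            raise ValueError("sizes must be non-negative")
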