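"""Position-occurrence profiles and machine-readable run summaries.

A profile counts, at every position of a query phage, how many detected
integrations across the whole dataset cover that position — highlighting the
regions of a phage that integrate most often. Each integration contributes at
most one count per position (its fragments' query intervals are unioned
first), so overlapping fragments of one joined integration are not double
counted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from pydantic import BaseModel, Field

from .defrag import query_coverage
from .model import Integration, OccurrenceProfile, SequenceCatalog

PathLike = Union[str, Path]

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# summary document schema (validated on write; JSON Schema in docs/)
# ---------------------------------------------------------------------------

class FragmentRecord(BaseModel):
    query_start: int = Field(ge=1)
    query_end: int = Field(ge=1)
    target_start: int = Field(ge=1)
    target_end: int = Field(ge=1)
    evalue: float = Field(ge=0)
    score: float


class IntegrationRecord(BaseModel):
    id: str
    phage: str
    start: int = Field(ge=1, description="genome span start, 1-based inclusive")
    end: int = Field(ge=1)
    strand: str = Field(pattern=r"^[+-]$")
    full_length: bool
    query_coverage_nt: int = Field(ge=1)
    fragments: list[FragmentRecord]


class GenomeSummary(BaseModel):
    integrations: list[IntegrationRecord]


class QueryExtent(BaseModel):
    """Extent of one integration on the query phage it matched."""

    id: str
    genome: str
    query_start: int = Field(ge=1)
    query_end: int = Field(ge=1)


class QuerySummary(BaseModel):
    length: int = Field(ge=1)
    counts: list[int]
    integrations: list[QueryExtent]


class RunSummary(BaseModel):
    schema_version: str
    genomes: dict[str, GenomeSummary]
    queries: dict[str, QuerySummary]


def _union_intervals(integration: Integration) -> list[tuple[int, int]]:
    intervals = sorted((m.query_start, m.query_end) for m in integration.fragments)
    merged = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start > merged[-1][1] + 1:
            merged.append([start, end])
        else:
            merged[-1][1] = max(merged[-1][1], end)
    return [(s, e) for s, e in merged]


def build_profiles(
    integrations: Iterable[Integration], catalog: SequenceCatalog
) -> dict[str, OccurrenceProfile]:
    """Build one occurrence profile per query phage with >= 1 integration.

    Raises if an integration references a query absent from the catalog.
    After building, the conservation identity sum(counts) == sum of the
    contributing integrations' query coverage is asserted.
    """
    counts: dict[str, np.ndarray] = {}
    coverage_total: dict[str, int] = {}
    for integ in integrations:
        if integ.query_id not in catalog:
            raise KeyError(f"integration {integ.integration_id}: query {integ.query_id!r} "
                           "absent from catalog")
        n = catalog.length_of(integ.query_id)
        vec = counts.setdefault(integ.query_id, np.zeros(n, dtype=np.int64))
        for start, end in _union_intervals(integ):
            if end > n:
                raise ValueError(
                    f"integration {integ.integration_id}: query interval {start}..{end} "
                    f"exceeds catalog length {n} of {integ.query_id}"
                )
            vec[start - 1 : end] += 1
        coverage_total[integ.query_id] = (
            coverage_total.get(integ.query_id, 0) + query_coverage(integ.fragments)
        )

    profiles: dict[str, OccurrenceProfile] = {}
    for query_id, vec in counts.items():
        assert int(vec.sum()) == coverage_total[query_id], "profile conservation violated"
        profiles[query_id] = OccurrenceProfile(
            query_id=query_id, length=len(vec), counts=[int(c) for c in vec]
        )
    return profiles


def export_summary_json(
    integrations: Iterable[Integration],
    profiles: Mapping[str, OccurrenceProfile],
    path: PathLike,
    catalog: Optional[SequenceCatalog] = None,
) -> RunSummary:
    """Serialize the run to a validated JSON document.

    Per genome: the integration records with their fragments. Per query: the
    occurrence counts array and the extent of each integration on the query.
    The document is validated against the pydantic schema before writing.
    """
    genomes: dict[str, GenomeSummary] = {}
    queries: dict[str, QuerySummary] = {}

    for query_id, prof in profiles.items():
        queries[query_id] = QuerySummary(
            length=prof.length, counts=list(prof.counts), integrations=[]
        )

    for integ in sorted(integrations, key=lambda i: (i.target_id, i.genome_span)):
        start, end = integ.genome_span
        record = IntegrationRecord(
            id=integ.integration_id,
            phage=integ.query_id,
            start=start,
            end=end,
            strand=integ.strand,
            full_length=integ.full_length,
            query_coverage_nt=integ.query_coverage_nt,
            fragments=[
                FragmentRecord(
                    query_start=m.query_start,
                    query_end=m.query_end,
                    target_start=m.target_start,
                    target_end=m.target_end,
                    evalue=m.evalue,
                    score=m.score,
                )
                for m in integ.fragments
            ],
        )
        genomes.setdefault(integ.target_id, GenomeSummary(integrations=[]))
        genomes[integ.target_id].integrations.append(record)
        if integ.query_id in queries:
            qs = min(m.query_start for m in integ.fragments)
            qe = max(m.query_end for m in integ.fragments)
            queries[integ.query_id].integrations.append(
                QueryExtent(
                    id=integ.integration_id,
                    genome=integ.target_id,
                    query_start=qs,
                    query_end=qe,
                )
            )

    summary = RunSummary(schema_version=SCHEMA_VERSION, genomes=genomes, queries=queries)
    with open(path, "w") as handle:
        json.dump(summary.model_dump(), handle, indent=1)
        handle.write("\n")
    return summary


def export_bed(integrations: Iterable[Integration], path: PathLike) -> None:
    """Write integrations as BED6 (0-based half-open; name = integration id;
    score = best fragment bit score clamped to [0, 1000])."""
    rows = []
    for integ in integrations:
        start, end = integ.genome_span
        best = max(m.score for m in integ.fragments)
        score = int(min(1000, max(0, round(best))))
        rows.append((integ.target_id, start - 1, end, integ.integration_id, score, integ.strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_json_schema(path: PathLike) -> None:
    """Emit the JSON Schema of the run-summary document (kept in docs/)."""
    with open(path, "w") as handle:
        json.dump(RunSummary.model_json_schema(), handle, indent=1)
        handle.write("\n")
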