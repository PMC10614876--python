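"""Match filtering and fragment joining.

Homology search tools report diverged prophage integrations as several nearby
alignment fragments. The joining step reassembles them: consecutive matches
on a genome are chained into one integration when they (A) hit the same query
phage on the same strand, (B) appear in the same order on query and genome,
(Ca) are separated on the genome by at most ``k * n`` nt (n = query length,
k = 0.25 by default), and (Cb) overlap on the query by at most θ = 50 nt.
Query *gaps* are never penalized — they may be large deletions in the
integrated copy.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .model import Integration, Match, PipelineConfig

__all__ = [
    "PipelineConfig",
    "Integration",
    "filter_matches",
    "joinable",
    "assign_integrations",
    "call_full_length",
    "query_coverage",
]


def filter_matches(
    matches: Sequence[Match], config: Optional[PipelineConfig] = None
) -> list[Match]:
    """Keep matches with E-value <= ``evalue_max`` and genome-side length
    >= ``min_match_length``. Order is preserved; the input is not modified."""
    cfg = config or PipelineConfig()
    return [
        m
        for m in matches
        if m.evalue <= cfg.evalue_max and m.target_span_nt >= cfg.min_match_length
    ]


def _query_overlap_nt(prev: Match, nxt: Match) -> int:
    """Overlap of consecutive fragments on the query, in nt (<= 0 means a gap).

    The adjacent query boundaries in genome order are prev.query_end /
    nxt.query_start on the plus strand and prev.query_start / nxt.query_end
    on the minus strand (where genome order reverses query order).
    """
    if prev.strand == "+":
        return prev.query_end - nxt.query_start + 1
    return nxt.query_end - prev.query_start + 1


def joinable(prev: Match, nxt: Match, config: Optional[PipelineConfig] = None) -> bool:
    """Decide whether two consecutive matches are fragments of one integration.

    ``prev`` must not start after ``nxt`` on the genome. Returns True iff all
    of the same-query/target/strand, colinearity, genome-gap and
    query-overlap criteria hold under ``config``.
    """
    cfg = config or PipelineConfig()
    if prev.target_start > nxt.target_start:
        raise ValueError(
            "joinable() requires prev.target_start <= next.target_start "
            f"({prev.target_start} > {nxt.target_start})"
        )
    # A: same query phage, same genome, same strand
    if (
        prev.query_id != nxt.query_id
        or prev.target_id != nxt.target_id
        or prev.strand != nxt.strand
    ):
        return False
    # B: same order on query and genome (mirrored on the minus strand)
    if prev.strand == "+":
        if nxt.query_start < prev.query_start or nxt.query_end < prev.query_end:
            return False
    else:
        if nxt.query_end > prev.query_end or nxt.query_start > prev.query_start:
            return False
    # Ca: near enough on the genome — |i - j| <= n * k
    n = prev.query_length if prev.query_length is not None else nxt.query_length
    if n is None:
        raise ValueError("joinable() requires query_length on at least one match")
    if abs(prev.target_end - nxt.target_start) > n * cfg.gap_fraction_k:
        return False
    # Cb: bounded overlap on the query; query gaps pass unconditionally
    if _query_overlap_nt(prev, nxt) > cfg.max_query_overlap_theta:
        return False
    return True


def query_coverage(fragments: Iterable[Match]) -> int:
    """Total nt of the query covered by the union of fragment query intervals."""
    intervals = sorted((m.query_start, m.query_end) for m in fragments)
    if not intervals:
        raise ValueError("query_coverage requires at least one fragment")
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end + 1:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    total += cur_end - cur_start + 1
    return total


def call_full_length(integration: Integration, config: Optional[PipelineConfig] = None) -> bool:
    """An integration is full length when its query coverage reaches
    ``full_length_fraction`` of the query length (inclusive: "at least")."""
    cfg = config or PipelineConfig()
    if integration.query_length is None:
        raise ValueError(
            f"integration {integration.integration_id}: query_length unknown, "
            "cannot call full-length status"
        )
    return integration.query_coverage_nt >= cfg.full_length_fraction * integration.query_length


def _build_integration(
    integration_id: str, fragments: list[Match], cfg: PipelineConfig
) -> Integration:
    coverage = query_coverage(fragments)
    qlen = fragments[0].query_length
    full = (
        coverage >= cfg.full_length_fraction * qlen if qlen is not None else False
    )
    return Integration(
        integration_id=integration_id,
        query_id=fragments[0].query_id,
        target_id=fragments[0].target_id,
        strand=fragments[0].strand,
        fragments=fragments,
        query_coverage_nt=coverage,
        full_length=full,
        query_length=qlen,
    )


def assign_integrations(
    matches: Sequence[Match], config: Optional[PipelineConfig] = None
) -> list[Integration]:
    """Partition filtered matches into integrations.

    Matches are grouped by (target, query, strand) so that, e.g., a hit to a
    different phage lying between two fragments does not break their chain
    (cross-query joins are impossible anyway). Within each group, matches
    sorted by genome position are scanned left to right; a match extends the
    current chain iff it is joinable with the chain's last fragment,
    otherwise it starts a new chain. Integration IDs are deterministic:
    ``<target_id>_<ordinal>`` numbered along the genome.
    """
    cfg = config or PipelineConfig()
    groups: dict[tuple[str, str, str], list[Match]] = defaultdict(list)
    for m in matches:
        groups[(m.target_id, m.query_id, m.strand)].append(m)

    chains_by_target: dict[str, list[list[Match]]] = defaultdict(list)
    for (target_id, _query_id, _strand), group in groups.items():
        ordered = sorted(group, key=lambda m: (m.target_start, m.target_end, m.query_start))
        chain: list[Match] = [ordered[0]]
        for m in ordered[1:]:
            if joinable(chain[-1], m, cfg):
                chain.append(m)
            else:
                chains_by_target[target_id].append(chain)
                chain = [m]
        chains_by_target[target_id].append(chain)

    integrations: list[Integration] = []
    for target_id in sorted(chains_by_target):
        chains = sorted(
            chains_by_target[target_id],
            key=lambda c: (
                min(m.target_start for m in c),
                max(m.target_end for m in c),
                c[0].query_id,
                c[0].strand,
            ),
        )
        for ordinal, chain in enumerate(chains, start=1):
            integrations.append(_build_integration(f"{target_id}_{ordinal}", chain, cfg))
    return integrations
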