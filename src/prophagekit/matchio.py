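"""Readers and writers: FASTA, nhmmer/BLAST hit tables, and the annotation TSV.

The nhmmer parser consumes HMMER's whitespace-delimited target-hits table
("tblout"); in this pipeline's dialect the *query* is a phage sequence and the
*target* is a bacterial genome/contig. The BLAST parser consumes the standard
12-column tabular format (``-outfmt 6``). Both normalize minus-strand hits so
that target coordinates ascend and orientation is carried by the strand flag.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import Integration, Match, SequenceCatalog, normalize_strand

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGTN")

#: Column order of the annotation TSV. One row per match fragment; fragments
#: of one joined integration share integration_id and full_length.
ANNOTATION_COLUMNS = [
    "phage_name",
    "evalue",
    "score",
    "query_start",
    "query_end",
    "target_name",
    "target_start",
    "target_end",
    "strand",
    "integration_id",
    "full_length",
]


def _clean_residues(raw: str, seq_id: str) -> str:
    """Upper-case and map anything outside {A,C,G,T,N} to N (with a warning)."""
    seq = raw.upper()
    if set(seq) <= VALID_BASES:
        return seq
    n_bad = sum(1 for c in seq if c not in VALID_BASES)
    logger.warning(
        "sequence %s: %d residue(s) outside {A,C,G,T,N} mapped to N", seq_id, n_bad
    )
    return "".join(c if c in VALID_BASES else "N" for c in seq)


def read_fasta(path: PathLike) -> SequenceCatalog:
    """Read a (multi-)FASTA file into a :class:`SequenceCatalog`.

    The record id is the first whitespace-delimited token of the header.
    Residues are upper-cased; ambiguity codes and other non-ACGTN characters
    become N. An empty file or a duplicate id is an error.
    """
    catalog = SequenceCatalog()
    for record in SeqIO.parse(str(path), "fasta"):
        residues = _clean_residues(str(record.seq), record.id)
        if not residues:
            raise ValueError(f"sequence {record.id!r} in {path} is empty")
        catalog.add(record.id, len(residues), residues)
    if len(catalog) == 0:
        raise ValueError(f"no sequences in {path}")
    return catalog


def write_fasta(catalog: SequenceCatalog, path: PathLike, width: int = 70) -> None:
    """Write a catalog's residues as wrapped FASTA (ids in sorted order)."""
    with open(path, "w") as handle:
        for seq_id in sorted(catalog):
            residues = catalog.residues_of(seq_id)
            handle.write(f">{seq_id}\n")
            for i in range(0, len(residues), width):
                handle.write(residues[i : i + width] + "\n")


def _resolve_query_length(
    query_id: str, qlen: Optional[int], catalog: Optional[SequenceCatalog], where: str
) -> int:
    if qlen is not None:
        return qlen
    if catalog is not None and query_id in catalog:
        return catalog.length_of(query_id)
    raise ValueError(f"{where}: query id {query_id!r} not in catalog and no qlen column")


def parse_nhmmer_tblout(
    path: PathLike, catalog: Optional[SequenceCatalog] = None
) -> list[Match]:
    """Parse an nhmmer target-hits table into normalized :class:`Match` records.

    Expected per-row fields (whitespace-delimited, ``#`` lines are comments)::

        target  t-acc  query  q-acc  hmmfrom  hmm_to  alifrom  ali_to
        envfrom  env_to  sq_len  strand  E-value  score  bias  [description]

    ``hmmfrom``/``hmm to`` are coordinates on the query phage (always
    ascending), ``alifrom``/``ali to`` on the genome (descending on the minus
    strand, normalized here). Query lengths come from ``catalog`` since the
    table records only the target length.
    """
    matches: list[Match] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 15:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 15 whitespace-delimited columns, "
                    f"got {len(fields)}"
                )
            target_id, query_id = fields[0], fields[2]
            try:
                hmm_from, hmm_to = int(fields[4]), int(fields[5])
                ali_from, ali_to = int(fields[6]), int(fields[7])
                evalue = float(fields[12])
                score = float(fields[13])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            strand = normalize_strand(fields[11])
            target_start, target_end = sorted((ali_from, ali_to))
            query_start, query_end = sorted((hmm_from, hmm_to))
            qlen = _resolve_query_length(query_id, None, catalog, f"{path}:{lineno}")
            matches.append(
                Match(
                    query_id=query_id,
                    target_id=target_id,
                    query_start=query_start,
                    query_end=query_end,
                    target_start=target_start,
                    target_end=target_end,
                    strand=strand,
                    evalue=evalue,
                    score=score,
                    query_length=qlen,
                    source="nhmmer",
                )
            )
    return matches


def parse_blast_tab(path: PathLike, catalog: SequenceCatalog) -> list[Match]:
    """Parse BLAST 12-column tabular output (query = phage, subject = genome).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore. Minus-strand hits (sstart > send) are normalized.
    The catalog is required: it supplies query lengths.
    """
    matches: list[Match] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) == 1:  # tolerate space-delimited variants
                fields = stripped.split()
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            query_id, subject_id = fields[0], fields[1]
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            strand = "-" if sstart > send else "+"
            target_start, target_end = sorted((sstart, send))
            query_start, query_end = sorted((qstart, qend))
            if query_id not in catalog:
                raise ValueError(f"{path}:{lineno}: unknown query id {query_id!r}")
            matches.append(
                Match(
                    query_id=query_id,
                    target_id=subject_id,
                    query_start=query_start,
                    query_end=query_end,
                    target_start=target_start,
                    target_end=target_end,
                    strand=strand,
                    evalue=evalue,
                    score=bitscore,
                    query_length=catalog.length_of(query_id),
                    source="blast",
                )
            )
    return matches


def write_annotation_tsv(integrations: Iterable[Integration], path: PathLike) -> None:
    """Write the per-genome annotation TSV: one row per fragment.

    Fragments of one integration share ``integration_id`` and the
    ``full_length`` flag (written as the literals ``True``/``False``). Rows
    are sorted by (target_name, target_start); coordinates are 1-based
    inclusive.
    """
    rows = []
    for integ in integrations:
        for frag in integ.fragments:
            rows.append(
                {
                    "phage_name": frag.query_id,
                    "evalue": frag.evalue,
                    "score": frag.score,
                    "query_start": frag.query_start,
                    "query_end": frag.query_end,
                    "target_name": frag.target_id,
                    "target_start": frag.target_start,
                    "target_end": frag.target_end,
                    "strand": frag.strand,
                    "integration_id": integ.integration_id,
                    "full_length": bool(integ.full_length),
                }
            )
    frame = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["target_name", "target_start"], kind="stable"
        ).reset_index(drop=True)
    # repr-based float formatting so evalue/score round-trip exactly
    frame["evalue"] = [repr(float(v)) for v in frame["evalue"]]
    frame["score"] = [repr(float(v)) for v in frame["score"]]
    frame.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: PathLike) -> list[Integration]:
    """Read an annotation TSV back into :class:`Integration` records.

    The integration partition is reconstructed from ``integration_id`` (row
    order does not matter). Query lengths are not stored in the TSV, so the
    returned matches carry ``query_length=None`` and ``full_length`` is taken
    from the file rather than recomputed.
    """
    # round_trip float parsing: the default C parser is lossy on E-values
    frame = pd.read_csv(
        path, sep="\t", dtype={"full_length": str}, float_precision="round_trip"
    )
    unknown = set(frame.columns) - set(ANNOTATION_COLUMNS)
    if unknown:
        raise ValueError(f"unknown column(s) in {path}: {sorted(unknown)}")
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing column(s) in {path}: {sorted(missing)}")

    from .defrag import query_coverage  # local import to avoid a cycle

    by_id: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in frame.to_dict("records"):
        iid = str(row["integration_id"])
        if iid not in by_id:
            by_id[iid] = []
            order.append(iid)
        by_id[iid].append(row)

    integrations: list[Integration] = []
    for iid in order:
        rows = by_id[iid]
        fragments = [
            Match(
                query_id=str(r["phage_name"]),
                target_id=str(r["target_name"]),
                query_start=int(r["query_start"]),
                query_end=int(r["query_end"]),
                target_start=int(r["target_start"]),
                target_end=int(r["target_end"]),
                strand=str(r["strand"]),
                evalue=float(r["evalue"]),
                score=float(r["score"]),
                query_length=None,
                source="tsv",
            )
            for r in rows
        ]
        flags = {str(r["full_length"]) for r in rows}
        if len(flags) != 1 or flags - {"True", "False"}:
            raise ValueError(f"inconsistent full_length values for integration {iid!r}")
        integrations.append(
            Integration(
                integration_id=iid,
                query_id=fragments[0].query_id,
                target_id=fragments[0].target_id,
                strand=fragments[0].strand,
                fragments=fragments,
                query_coverage_nt=query_coverage(fragments),
                full_length=flags.pop() == "True",
                query_length=None,
            )
        )
    return integrations
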