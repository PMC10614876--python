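"""FASTA reading, hit-table parsing (incl. against real nhmmer/blastn output),
and annotation-TSV round trips."""

import logging
import random
import subprocess

import pytest

from prophagekit import (
    SimConfig,
    assign_integrations,
    filter_matches,
    parse_blast_tab,
    parse_nhmmer_tblout,
    read_annotation_tsv,
    read_fasta,
    simulate_dataset,
    write_annotation_tsv,
    write_fasta,
)

from conftest import mk_match

TBLOUT_HEADER = (
    "# target name  accession  query name  accession  hmmfrom  hmm to  alifrom  "
    "ali to  envfrom  env to  sq len  strand  E-value  score  bias  description\n"
)


def tblout_line(target, query, hmmfrom, hmmto, alifrom, alito, strand, evalue, score):
    return (
        f"{target} - {query} - {hmmfrom} {hmmto} {alifrom} {alito} "
        f"{min(alifrom, alito)} {max(alifrom, alito)} 50000 {strand} {evalue} {score} 0.0 -\n"
    )


class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">q1\nACGT\n")
        cat = read_fasta(p)
        assert cat.length_of("q1") == 4
        assert cat.residues_of("q1") == "ACGT"

    def test_header_token_and_multiline(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a x\nAC\nGT\n>b\nNNN\n")
        cat = read_fasta(p)
        assert set(cat) == {"a", "b"}
        assert (cat.length_of("a"), cat.length_of("b")) == (4, 3)

    def test_ambiguity_codes_become_n_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgu\n")
        with caplog.at_level(logging.WARNING):
            cat = read_fasta(p)
        assert cat.residues_of("a") == "ACGN"
        assert any("mapped to N" in rec.message for rec in caplog.records)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_fasta(p)

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="a"):
            read_fasta(p)


class TestParseNhmmerTblout:
    def test_comment_only_file_is_empty(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(TBLOUT_HEADER + "#\n")
        assert parse_nhmmer_tblout(p) == []

    def test_plus_strand_row(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(TBLOUT_HEADER + tblout_line("gnm", "ph", 1, 2001, 7000, 9000, "+", "1e-30", 55.0))
        cat = _catalog_with(ph=4000)
        (m,) = parse_nhmmer_tblout(p, cat)
        assert (m.target_start, m.target_end, m.strand) == (7000, 9000, "+")
        assert (m.query_start, m.query_end) == (1, 2001)
        assert m.evalue == 1e-30 and m.query_length == 4000

    def test_minus_strand_coordinates_normalized(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(TBLOUT_HEADER + tblout_line("gnm", "ph", 1, 2001, 9000, 7000, "-", "1e-30", 55.0))
        (m,) = parse_nhmmer_tblout(p, _catalog_with(ph=4000))
        assert (m.target_start, m.target_end, m.strand) == (7000, 9000, "-")

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(TBLOUT_HEADER + "gnm - ph - 1 10\n")
        with pytest.raises(ValueError, match=":2"):
            parse_nhmmer_tblout(p, _catalog_with(ph=4000))

    def test_unknown_query_id_errors(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(tblout_line("gnm", "mystery", 1, 10, 1, 10, "+", "0", 5.0))
        with pytest.raises(ValueError, match="mystery"):
            parse_nhmmer_tblout(p, _catalog_with(ph=4000))


class TestParseBlastTab:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("")
        assert parse_blast_tab(p, _catalog_with(ph=4000)) == []

    def test_minus_strand_normalized(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("ph\tgnm\t99.0\t401\t4\t0\t1\t401\t500\t100\t1e-50\t700\n")
        (m,) = parse_blast_tab(p, _catalog_with(ph=4000))
        assert (m.target_start, m.target_end, m.strand) == (100, 500, "-")

    def test_query_coordinates_pass_through(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("ph\tgnm\t99.0\t4000\t4\t0\t1\t4000\t100\t4099\t1e-50\t700\n")
        (m,) = parse_blast_tab(p, _catalog_with(ph=4000))
        assert (m.query_start, m.query_end, m.strand) == (1, 4000, "+")
        assert m.evalue == 1e-50 and m.query_length == 4000

    def test_unknown_query_errors(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("who\tgnm\t99.0\t10\t0\t0\t1\t10\t1\t10\t0.0\t20\n")
        with pytest.raises(ValueError, match="who"):
            parse_blast_tab(p, _catalog_with(ph=4000))


def _catalog_with(**lengths):
    from prophagekit import SequenceCatalog

    cat = SequenceCatalog()
    for name, length in lengths.items():
        cat.add(name, length)
    return cat


@pytest.fixture(scope="module")
def fixture_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("realtools")
    cfg = SimConfig(
        genome_length=20_000, query_length=3_000, n_integrations=2, n_queries=1,
        p_full=1.0, p_truncated=0.0, p_fragmented=0.0, seed=7,
    )
    genome, queries, truths = simulate_dataset(cfg)
    write_fasta(genome, out / "genome.fa")
    write_fasta(queries, out / "query.fa")
    return out, queries, truths


class TestRealToolCrossCheck:
    """nhmmer (HMMER 3.4) and blastn as independent oracles for the parsers."""

    def test_nhmmer_output_parses_to_truth_coordinates(self, fixture_run):
        out, queries, truths = fixture_run
        subprocess.run(
            ["nhmmer", "--tblout", str(out / "hits.tbl"), "-o", "/dev/null",
             str(out / "query.fa"), str(out / "genome.fa")],
            check=True,
        )
        matches = parse_nhmmer_tblout(out / "hits.tbl", queries)
        integrations = assign_integrations(filter_matches(matches))
        spans = {i.strand: i.genome_span for i in integrations}
        for t in truths:
            ts, te = t.genome_span
            ps, pe = spans[t.strand]
            assert abs(ps - ts) <= 5 and abs(pe - te) <= 5

    def test_blastn_output_parses_to_truth_coordinates(self, fixture_run):
        out, queries, truths = fixture_run
        result = subprocess.run(
            ["blastn", "-query", str(out / "query.fa"), "-subject", str(out / "genome.fa"),
             "-outfmt", "6"],
            check=True, capture_output=True, text=True,
        )
        (out / "blast.tsv").write_text(result.stdout)
        matches = parse_blast_tab(out / "blast.tsv", queries)
        by_strand = {m.strand: m for m in matches}
        for t in truths:
            m = by_strand[t.strand]
            assert (m.target_start, m.target_end) == t.genome_span


class TestAnnotationTsv:
    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "ann.tsv"
        write_annotation_tsv([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("phage_name\t")

    def test_single_integration_one_row(self, tmp_path):
        ints = assign_integrations([mk_match(1, 100, 500, 599, query_length=100)])
        p = tmp_path / "ann.tsv"
        write_annotation_tsv(ints, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2
        assert lines[1].split("\t")[-2] == "tg_1"

    def test_joined_fragments_share_id_and_flag(self, tmp_path):
        ints = assign_integrations(
            [
                mk_match(1, 4900, 100, 5000, score=10.0),
                mk_match(4950, 6950, 7000, 9000, score=20.0),
            ]
        )
        assert len(ints) == 1
        p = tmp_path / "ann.tsv"
        write_annotation_tsv(ints, p)
        rows = [line.split("\t") for line in p.read_text().splitlines()[1:]]
        assert len(rows) == 2
        assert rows[0][-2] == rows[1][-2] and rows[0][-1] == rows[1][-1]

    def test_round_trip_reproduces_partition_and_fields(self, tmp_path):
        matches = [
            mk_match(1, 4900, 100, 5000, evalue=1e-30, score=12.5),
            mk_match(4950, 6950, 7000, 9000, evalue=2e-8, score=7.25),
            mk_match(200, 900, 20_000, 20_700, strand="-", query_id="other"),
        ]
        original = assign_integrations(matches)
        p = tmp_path / "ann.tsv"
        write_annotation_tsv(original, p)
        restored = read_annotation_tsv(p)
        assert len(restored) == len(original)
        by_id = {i.integration_id: i for i in restored}
        for integ in original:
            back = by_id[integ.integration_id]
            assert back.full_length == integ.full_length
            for a, b in zip(integ.fragments, back.fragments):
                assert (a.query_start, a.query_end, a.target_start, a.target_end) == (
                    b.query_start, b.query_end, b.target_start, b.target_end,
                )
                assert a.evalue == b.evalue and a.score == b.score
                assert a.strand == b.strand and a.query_id == b.query_id

    def test_shuffled_rows_reconstruct_same_grouping(self, tmp_path):
        original = assign_integrations(
            [
                mk_match(1, 4900, 100, 5000),
                mk_match(4950, 6950, 7000, 9000),
                mk_match(200, 900, 20_000, 20_700, strand="-"),
            ]
        )
        p = tmp_path / "ann.tsv"
        write_annotation_tsv(original, p)
        header, *rows = p.read_text().splitlines()
        random.Random(0).shuffle(rows)
        shuffled = tmp_path / "shuffled.tsv"
        shuffled.write_text("\n".join([header, *rows]) + "\n")
        restored = read_annotation_tsv(shuffled)
        want = {
            (i.integration_id, tuple((m.target_start, m.target_end) for m in i.fragments))
            for i in original
        }
        got = {
            (i.integration_id, tuple((m.target_start, m.target_end) for m in i.fragments))
            for i in restored
        }
        assert got == want

    def test_unknown_column_errors(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("phage_name\tmystery_col\nph\t1\n")
        with pytest.raises(ValueError, match="mystery_col"):
            read_annotation_tsv(p)
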