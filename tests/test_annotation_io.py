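"""Parsers and homology-annotation filtering."""

import pytest

from kleptorecept.annotation_io import (
    AnnotationError,
    AnnotationRecord,
    PipelineConfig,
    ProteinRecord,
    filter_annotations,
    parse_domain_hits,
    parse_tm_regions,
    read_fasta,
    write_fasta,
)
from kleptorecept.synthetic_data import generate_homology_table


# ---------------------------------------------------------------------------
# FASTA


def test_read_fasta_identity(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">a\nMKV\n>b\nMKVLW\nAC\n>short149\n" + "A" * 149 + "\n")
    records = read_fasta(p)
    assert [r.id for r in records] == ["a", "b", "short149"]
    assert [r.length for r in records] == [3, 7, 149]  # no length filtering here


def test_read_fasta_duplicate_id_is_hard_error(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">a\nMKV\n>a\nMKW\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        read_fasta(p)


def test_empty_sequence_names_the_record():
    with pytest.raises(AnnotationError, match="prot7"):
        ProteinRecord(id="prot7", sequence="")


def test_fasta_round_trip(small_proteome, tmp_path):
    out = tmp_path / "rt.fasta"
    write_fasta(small_proteome.proteins, out)
    back = read_fasta(out)
    assert [(r.id, r.sequence) for r in back] == [
        (r.id, r.sequence) for r in small_proteome.proteins
    ]


# ---------------------------------------------------------------------------
# domtblout

_DOMTBL = """\
# comment line
CD36 PF01130.1 330 prot1 - 500 1e-30 250.0 0.1 1 1 1e-30 1e-30 250.0 0.1 1 330 40 380 40 380 0.95 desc here
Lectin_C PF00059.1 115 prot2 - 400 1e-12 80.0 0.1 1 1 1e-12 2e-12 80.0 0.1 1 115 10 120 8 125 0.90 another
"""


def test_parse_domain_hits_field_mapping(tmp_path):
    p = tmp_path / "d.domtblout"
    p.write_text(_DOMTBL)
    hits = parse_domain_hits(p)
    assert len(hits) == 2
    h = hits[0]
    assert (h.protein_id, h.domain_name, h.accession) == ("prot1", "CD36", "PF01130.1")
    assert h.i_evalue == 1e-30
    assert (h.start, h.end) == (40, 380)  # envelope, not alignment, coordinates
    assert hits[1].i_evalue == 2e-12
    assert (hits[1].start, hits[1].end) == (8, 125)


def test_parse_domain_hits_comment_only(tmp_path):
    p = tmp_path / "d.domtblout"
    p.write_text("# only\n# comments\n")
    assert parse_domain_hits(p) == []


def test_parse_domain_hits_short_row_reports_line(tmp_path):
    p = tmp_path / "d.domtblout"
    p.write_text("CD36 PF01130.1 330 prot1\n")
    with pytest.raises(AnnotationError, match=":1"):
        parse_domain_hits(p)


def test_parse_domain_hits_negative_coordinates(tmp_path):
    bad = _DOMTBL.replace(" 40 380 0.95", " -4 380 0.95")
    p = tmp_path / "d.domtblout"
    p.write_text(bad)
    with pytest.raises(AnnotationError):
        parse_domain_hits(p)


def test_generator_domtbl_round_trip(small_proteome):
    parsed = parse_domain_hits(small_proteome.domtbl_path)
    planted = small_proteome.hits
    assert len(parsed) == len(planted)  # no row silently dropped
    key = lambda h: (h.protein_id, h.start, h.end, h.domain_name)
    assert sorted(key(h) for h in parsed) == sorted(key(h) for h in planted)


# ---------------------------------------------------------------------------
# TMHMM


def test_parse_tm_regions_long_dialect(tmp_path):
    p = tmp_path / "tm.txt"
    p.write_text(
        "prot1\tTMHMM2.0\toutside\t1\t6\n"
        "prot1\tTMHMM2.0\tTMhelix\t7\t29\n"
        "prot1\tTMHMM2.0\tinside\t30\t500\n"
    )
    regions = parse_tm_regions(p)
    assert len(regions) == 1
    assert (regions[0].protein_id, regions[0].start, regions[0].end) == ("prot1", 7, 29)


def test_parse_tm_regions_short_dialect(tmp_path):
    p = tmp_path / "tm.txt"
    p.write_text("prot1\tlen=500\tExpAA=44\tFirst60=20\tPredHel=2\tTopology=o7-29i40-62o\n")
    regions = parse_tm_regions(p)
    assert [(r.start, r.end) for r in regions] == [(7, 29), (40, 62)]


def test_zero_helices_is_fine(tmp_path):
    p = tmp_path / "tm.txt"
    p.write_text("prot1\tlen=300\tExpAA=0\tFirst60=0\tPredHel=0\tTopology=o\n")
    assert parse_tm_regions(p) == []


def test_unknown_dialect_reports_offending_line(tmp_path):
    p = tmp_path / "tm.txt"
    p.write_text("what is this line\n")
    with pytest.raises(AnnotationError, match="what is this"):
        parse_tm_regions(p)


def test_overlapping_helices_rejected(tmp_path):
    p = tmp_path / "tm.txt"
    p.write_text(
        "prot1\tTMHMM2.0\tTMhelix\t7\t29\nprot1\tTMHMM2.0\tTMhelix\t20\t45\n"
    )
    with pytest.raises(AnnotationError, match="overlap"):
        parse_tm_regions(p)


def test_generator_tm_round_trip(small_proteome):
    parsed = parse_tm_regions(small_proteome.tmhmm_path)
    key = lambda t: (t.protein_id, t.start, t.end)
    assert sorted(key(t) for t in parsed) == sorted(key(t) for t in small_proteome.tms)


# ---------------------------------------------------------------------------
# homology-annotation filter


def _rec(pid, evalue, group, sid="S1"):
    return AnnotationRecord(
        protein_id=pid, subject_id=sid, description="d", evalue=evalue, taxon_group=group
    )


def test_filter_keeps_strong_metazoan(config):
    assert filter_annotations([_rec("p", 1e-12, "metazoa")], config) != []


def test_filter_drops_weak_metazoan(config):
    # threshold is 1e-10: an E-value of 1e-8 is not good enough
    assert filter_annotations([_rec("p", 1e-8, "metazoa")], config) == []


def test_filter_drops_non_metazoa_and_unknown(config):
    records = [_rec("p1", 1e-20, "non_metazoa"), _rec("p2", 1e-20, "unknown")]
    assert filter_annotations(records, config) == []


def test_filter_planted_bookkeeping(config):
    records, _ = generate_homology_table(100, 40, seed=3)
    kept = filter_annotations(records, config)
    assert len(kept) == 40
    assert all(r.taxon_group == "metazoa" and r.evalue <= 1e-10 for r in kept)


def test_filter_is_idempotent(config):
    records, _ = generate_homology_table(60, 25, seed=4)
    once = filter_annotations(records, config)
    assert filter_annotations(once, config) == once


def test_filter_monotone_in_threshold():
    records, _ = generate_homology_table(100, 40, seed=5)
    n_prev = None
    for thr in (1e-8, 1e-10, 1e-15, 1e-25):
        n = len(filter_annotations(records, PipelineConfig(blast_evalue_max=thr)))
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_best_hit_default_vs_keep_all(config):
    records = [
        _rec("p", 1e-30, "non_metazoa", sid="S_non"),
        _rec("p", 1e-20, "metazoa", sid="S_met"),
    ]
    # best hit is non-metazoan -> protein dropped under the default
    assert filter_annotations(records, config) == []
    kept = filter_annotations(records, config, keep_all_hits=True)
    assert [r.subject_id for r in kept] == ["S_met"]


def test_config_rejects_nonpositive_thresholds():
    with pytest.raises(ValueError):
        PipelineConfig(min_protein_length=0)
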