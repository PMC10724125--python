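"""Plastome ingestion: GenBank I/O, CDS extraction, genome structure."""

import textwrap

import pytest

from araliome.plastome import (DEFAULT_EXCLUDE, GenomeRecord, Feature,
                               detect_quadripartite, extract_cds, gc_content,
                               normalize_gene_name, read_genbank,
                               reverse_complement, write_genbank,
                               InternalStopWarning, ParseError)
from araliome._codons import translate_codon


def _toy_genbank(tmp_path, feature_lines, seq="ACGT" * 20):
    """Minimal hand-built GenBank record."""
    lines = [
        f"LOCUS       TOY                {len(seq)} bp    DNA     circular"
        "     PLN 01-JAN-2020",
        "DEFINITION  toy record.",
        "ACCESSION   TOY1",
        "VERSION     TOY1",
        "SOURCE      test",
        "  ORGANISM  Testus toyus",
        "FEATURES             Location/Qualifiers",
    ]
    lines += feature_lines
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    path = tmp_path / "toy.gb"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_read_genbank_join_coordinates(tmp_path):
    """A join() CDS becomes one feature with two 0-based intervals."""
    path = _toy_genbank(tmp_path, [
        "     CDS             join(10..18,30..38)",
        '                     /gene="g1"',
        '                     /codon_start=1',
    ])
    (rec,) = read_genbank(path)
    assert rec.topology == "circular"
    (feat,) = rec.features
    assert feat.intervals == [(9, 18, "+"), (29, 38, "+")]
    assert feat.spliced_length == 18


def test_read_genbank_complement_extracts_revcomp(tmp_path):
    seq = "A" * 9 + "ACGTACGTA" + "A" * 62
    path = _toy_genbank(tmp_path, [
        "     CDS             complement(10..18)",
        '                     /gene="g1"',
    ], seq=seq)
    (rec,) = read_genbank(path)
    (feat,) = rec.features
    assert feat.strand == "-"
    assert rec.splice(feat) == reverse_complement("ACGTACGTA")


def test_read_genbank_malformed_raises(tmp_path):
    path = tmp_path / "bad.gb"
    path.write_text("LOCUS garbage\nnot a record\n")
    with pytest.raises(ParseError):
        read_genbank(path)


def test_genbank_round_trip_identity(tmp_path, toy_plastome):
    """read -> write -> read preserves sequence and coordinates exactly."""
    record, _ = toy_plastome
    p1 = tmp_path / "a.gb"
    write_genbank([record], p1)
    (rec2,) = read_genbank(p1)
    p2 = tmp_path / "b.gb"
    write_genbank([rec2], p2)
    (rec3,) = read_genbank(p2)
    assert rec2.sequence == record.sequence == rec3.sequence
    assert [(f.gene, f.kind, f.intervals, f.codon_start)
            for f in rec2.features] == \
        [(f.gene, f.kind, f.intervals, f.codon_start)
         for f in record.features]
    assert rec2.topology == "circular"


@pytest.mark.parametrize("raw,expected", [
    ("RBCL", "rbcL"),
    ("psbA ", "psbA"),
    ("ycf15", "ycf15"),
    ("Rps12", "rps12"),
    ("unknownGene", "unknownGene"),
])
def test_normalize_gene_name(raw, expected):
    assert normalize_gene_name(raw) == expected


@pytest.mark.parametrize("seq,expected", [
    ("ATGC", 0.5),
    ("AAAA", 0.0),
    # ambiguity codes excluded from numerator and denominator
    ("ATGNNC", 0.5),
    ("GGCC", 1.0),
])
def test_gc_content(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_undefined_on_all_ambiguous():
    with pytest.raises(ValueError):
        gc_content("NNNN")


class TestExtractCds:
    def _record(self, cds, codon_start=1, gene="g1"):
        return GenomeRecord(id="r", taxon="t", sequence=cds + "AAAA",
                            features=[Feature(gene=gene, kind="CDS",
                                              intervals=[(0, len(cds), "+")],
                                              codon_start=codon_start)])

    def test_in_frame_passthrough(self):
        out = extract_cds(self._record("ATGAAATAA"))
        assert out["g1"] == "ATGAAATAA"

    def test_codon_start_trimming(self):
        # codon_start 2 drops one leading base, then the trailing partial
        out = extract_cds(self._record("ATGAAATAA", codon_start=2))
        assert out["g1"] == "TGAAAT"

    def test_default_exclusion_list(self):
        out = extract_cds(self._record("ATGAAATAA", gene="rps12"))
        assert "rps12" not in out
        out = extract_cds(self._record("ATGAAATAA", gene="rps12"),
                          exclude=set())
        assert "rps12" in out

    def test_internal_stop_warns(self):
        with pytest.warns(InternalStopWarning):
            extract_cds(self._record("ATGTAAAAATAA"))

    def test_ir_duplicated_gene_kept_once(self):
        seq = "ATGAAATAA" + "C" * 10 + "ATGCCCTAA" + "CC"
        rec = GenomeRecord(id="r", taxon="t", sequence=seq, features=[
            Feature(gene="g1", kind="CDS", intervals=[(0, 9, "+")]),
            Feature(gene="g1", kind="CDS", intervals=[(19, 28, "+")]),
        ])
        out = extract_cds(rec)
        assert out["g1"] == "ATGAAATAA"  # first copy by position

    def test_simulated_cds_translate_clean(self, toy_plastome):
        """Toy-genome CDS are stop-free by construction after extraction."""
        record, truth = toy_plastome
        out = extract_cds(record)
        assert set(out) == set(truth["genes"]) - DEFAULT_EXCLUDE
        for gene, seq in out.items():
            assert seq == truth["genes"][gene]
            aas = [translate_codon(seq[i:i + 3])
                   for i in range(0, len(seq), 3)]
            assert "*" not in aas[:-1]


class TestQuadripartite:
    def test_planted_ir_recovered(self, toy_plastome):
        record, truth = toy_plastome
        qs = detect_quadripartite(record, min_ir=1000)
        assert qs.found
        assert qs.ir_length == truth["ir_length"]
        assert qs.lsc_length == truth["lsc_length"]
        assert qs.ssc_length == truth["ssc_length"]

    def test_region_lengths_tile_genome(self, toy_plastome):
        record, _ = toy_plastome
        qs = detect_quadripartite(record, min_ir=1000)
        assert qs.lsc_length + qs.ssc_length + 2 * qs.ir_length == len(record)

    def test_rotation_invariance(self, toy_plastome):
        """Detection sees the circle, not the arbitrary linearization."""
        record, truth = toy_plastome
        for shift in (137, truth["ira"][0] + truth["ir_length"] // 2):
            rot = GenomeRecord(id="rot", taxon=record.taxon,
                               sequence=record.sequence[shift:]
                               + record.sequence[:shift])
            qs = detect_quadripartite(rot, min_ir=1000)
            assert qs.found
            assert qs.ir_length == truth["ir_length"]
            assert {qs.lsc_length, qs.ssc_length} == \
                {truth["lsc_length"], truth["ssc_length"]}

    def test_reverse_complement_invariance(self, toy_plastome):
        record, truth = toy_plastome
        rc = GenomeRecord(id="rc", taxon=record.taxon,
                          sequence=reverse_complement(record.sequence))
        qs = detect_quadripartite(rc, min_ir=1000)
        assert qs.found and qs.ir_length == truth["ir_length"]

    def test_no_repeat_reports_no_ir(self):
        import numpy as np
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        rec = GenomeRecord(id="r", taxon="t", sequence=seq)
        qs = detect_quadripartite(rec, min_ir=1000)
        assert not qs.found
        assert qs.ir_length == 0
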