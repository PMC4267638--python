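"""scSNV enumeration, variant classification, db round-trip, VCF annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scsnv.genome_db import (
    GeneModel,
    ScsnvRecord,
    annotate_vcf,
    attach_scores,
    classify_variant,
    enumerate_scsnvs,
    query,
    read_db,
    read_gene_models,
    write_db,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def flat_genome(length=400, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), length))}


@pytest.fixture
def two_exon_plus():
    # exon1 51-110, intron 111-230, exon2 231-290
    return GeneModel("tx1", "chr1", "+", [(51, 110), (231, 290)], "g1")


class TestGeneModel:
    def test_intron_extraction(self, two_exon_plus):
        assert two_exon_plus.introns() == [(111, 230)]

    def test_minus_strand_introns(self):
        m = GeneModel("tx2", "chr1", "-", [(231, 290), (51, 110)], "g1")
        assert m.introns() == [(111, 230)]

    def test_single_exon_no_introns(self):
        assert GeneModel("tx", "chr1", "+", [(10, 50)]).introns() == []

    def test_validation(self):
        with pytest.raises(ValueError, match="transcription order"):
            GeneModel("t", "chr1", "+", [(100, 150), (10, 50)])
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("t", "chr1", "+", [(10, 50), (40, 80)])
        with pytest.raises(ValueError, match="strand"):
            GeneModel("t", "chr1", "*", [(10, 50)])


class TestEnumerate:
    def test_two_exon_count_is_63(self, two_exon_plus):
        recs = enumerate_scsnvs([two_exon_plus], flat_genome())
        assert len(recs) == 63
        assert len({r.pos for r in recs}) == 21
        donor = [r for r in recs if r.site_kind == "donor"]
        acceptor = [r for r in recs if r.site_kind == "acceptor"]
        assert len(donor) == 27 and len(acceptor) == 36

    def test_gt_ag_positions_absent(self, two_exon_plus):
        recs = enumerate_scsnvs([two_exon_plus], flat_genome())
        positions = {r.pos for r in recs}
        # intron 111-230: GT at 111,112; AG at 229,230
        assert positions.isdisjoint({111, 112, 229, 230})
        # window edges present: donor -3 (108), +8 (118); acceptor -12 (219), +2 (232)
        assert {108, 118, 219, 232} <= positions

    def test_ref_matches_genome(self, two_exon_plus):
        genome = flat_genome()
        recs = enumerate_scsnvs([two_exon_plus], genome)
        assert all(genome["chr1"][r.pos - 1] == r.ref for r in recs)
        assert all(r.ref != r.alt for r in recs)

    def test_minus_strand_positions_mirror_reverse_complement(self):
        """A minus-strand gene enumerates the same plus-strand positions as
        the equivalent gene on the reverse-complemented genome."""
        genome = flat_genome(length=400, seed=1)
        L = 400
        minus = GeneModel("tm", "chr1", "-", [(231, 290), (51, 110)], "g")
        recs_minus = enumerate_scsnvs([minus], genome)
        # same structure built on the reverse complement, plus strand
        rc = genome["chr1"][::-1].translate(COMPLEMENT)
        flip = lambda s, e: (L - e + 1, L - s + 1)
        plus_rc = GeneModel("tp", "chr1", "+", [flip(231, 290), flip(51, 110)], "g")
        recs_rc = enumerate_scsnvs([plus_rc], {"chr1": rc})
        mapped = {(L - r.pos + 1, r.ref.translate(COMPLEMENT), r.alt.translate(COMPLEMENT))
                  for r in recs_rc}
        assert {(r.pos, r.ref, r.alt) for r in recs_minus} == mapped

    def test_single_exon_yields_nothing(self):
        m = GeneModel("tx", "chr1", "+", [(51, 110)])
        assert enumerate_scsnvs([m], flat_genome()) == []

    def test_shared_intron_merges_transcripts(self, two_exon_plus):
        twin = GeneModel("tx1b", "chr1", "+", [(51, 110), (231, 290)], "g1")
        recs = enumerate_scsnvs([two_exon_plus, twin], flat_genome())
        assert len(recs) == 63
        assert all(r.transcript_ids == ("tx1", "tx1b") for r in recs)

    def test_exon_outside_bounds_rejected(self):
        m = GeneModel("tx", "chr1", "+", [(51, 110), (380, 450)])
        with pytest.raises(ValueError, match="outside"):
            enumerate_scsnvs([m], flat_genome(length=400))
        with pytest.raises(KeyError, match="chromosome"):
            enumerate_scsnvs([GeneModel("t", "chrX", "+", [(1, 5), (30, 40)])],
                             flat_genome())

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(2, 5), st.integers(0, 1000))
    def test_record_count_scales_with_introns(self, n_exons, seed):
        rng = np.random.default_rng(seed)
        strand = "+" if rng.random() < 0.5 else "-"
        exons, pos = [], 50
        for _ in range(n_exons):
            end = pos + int(rng.integers(20, 40))
            exons.append((pos, end))
            pos = end + int(rng.integers(31, 60))
        if strand == "-":
            exons = exons[::-1]
        genome = {"chr1": "".join(rng.choice(list("ACGT"), pos + 100))}
        m = GeneModel("tx", "chr1", strand, exons)
        recs = enumerate_scsnvs([m], genome)
        assert len(recs) == 63 * (n_exons - 1)


class TestClassify:
    def test_donor_plus3_intronic(self, two_exon_plus):
        hits = classify_variant("chr1", 113, "A", "C", [two_exon_plus])
        assert hits == [("donor", 3, "intronic")]

    def test_gt_position_excluded(self, two_exon_plus):
        assert classify_variant("chr1", 111, "G", "A", [two_exon_plus]) == []
        assert classify_variant("chr1", 230, "G", "A", [two_exon_plus]) == []

    def test_non_snv_excluded(self, two_exon_plus):
        assert classify_variant("chr1", 113, "AT", "A", [two_exon_plus]) == []
        assert classify_variant("chr1", 113, "A", "A", [two_exon_plus]) == []

    def test_short_exon_hits_both_windows(self):
        # middle exon of 4 nt sits in the upstream acceptor (+1,+2) and
        # downstream donor (-3..-1) windows simultaneously
        m = GeneModel("tx", "chr1", "+", [(51, 90), (151, 154), (231, 290)])
        hits = classify_variant("chr1", 152, "A", "C", [m])
        kinds = {h[0] for h in hits}
        assert kinds == {"acceptor", "donor"}
        assert ("acceptor", 2, "exonic") in hits
        assert ("donor", -3, "exonic") in hits

    def test_ref_mismatch_warns(self, two_exon_plus):
        genome = flat_genome()
        pos = 113
        wrong = "A" if genome["chr1"][pos - 1] != "A" else "C"
        with pytest.warns(UserWarning, match="reference"):
            hits = classify_variant("chr1", pos, wrong, "G", [two_exon_plus], genome)
        assert hits  # still classified, mismatch reported as warning


class TestDbFormat:
    def test_roundtrip(self, tmp_path, two_exon_plus):
        recs = enumerate_scsnvs([two_exon_plus], flat_genome())
        scored = attach_scores(recs, np.linspace(0, 1, 63), [None] * 63)
        path = tmp_path / "toy.db"
        write_db(scored, path)
        back = read_db(path)
        assert [r.key for r in back] == [r.key for r in scored]
        assert [r.site_kind for r in back] == [r.site_kind for r in scored]
        assert [r.region_side for r in back] == [r.region_side for r in scored]
        assert all(b.rf_score is None for b in back)
        # byte-identical re-serialization
        path2 = tmp_path / "toy2.db"
        write_db(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_unsorted_rejected(self, tmp_path):
        recs = [
            ScsnvRecord("chr1", 100, "A", "C", site_kind="donor", offset=3),
            ScsnvRecord("chr1", 50, "G", "T", site_kind="donor", offset=4),
        ]
        with pytest.raises(ValueError, match="sorted"):
            write_db(recs, tmp_path / "bad.db")

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "mangled.db"
        path.write_text("#chr\tpos\tref\talt\ttx\tens\tsite\toff\tada\trf\n"
                        "chr1\tNOTANUMBER\tA\tC\ttx\t.\tdonor\t3\t.\t.\n")
        with pytest.raises(ValueError, match=":2"):
            read_db(path)

    def test_query_variant_and_region(self, two_exon_plus):
        recs = enumerate_scsnvs([two_exon_plus], flat_genome())
        r0 = recs[0]
        assert query(recs, r0.chrom, r0.pos, r0.ref, r0.alt) == [r0]
        # GT-AG positions never present
        assert query(recs, "chr1", 111) == []
        window = query(recs, region=("chr1", 108, 121))
        assert {r.pos for r in window} == {108, 109, 110, 113, 114, 115, 116,
                                           117, 118}


class TestVcfAnnotation:
    VCF_HEADER = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=400>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )

    def test_annotate_overlapping_records(self, tmp_path, two_exon_plus):
        genome = flat_genome()
        recs = enumerate_scsnvs([two_exon_plus], genome)
        scored = attach_scores(recs, [0.9] * len(recs), [0.8] * len(recs))
        base = genome["chr1"]
        alt_of = lambda p: "A" if base[p - 1] != "A" else "C"
        # 3 inside consensus windows, 2 outside
        vcf_pos = [108, 113, 232, 10, 300]
        lines = [
            f"chr1\t{p}\t.\t{base[p-1]}\t{alt_of(p)}\t.\t.\t.\n" for p in vcf_pos
        ]
        vin = tmp_path / "in.vcf"
        vin.write_text(self.VCF_HEADER + "".join(lines))
        vout = tmp_path / "out.vcf"
        n = annotate_vcf(vin, scored, vout)
        assert n == 3
        out_lines = [l for l in vout.read_text().splitlines() if not l.startswith("#")]
        assert len(out_lines) == 5
        # ordering preserved; non-matching untouched
        assert [l.split("\t")[1] for l in out_lines] == [str(p) for p in vcf_pos]
        assert "SCSNV_ADA=0.9" in out_lines[0]
        assert "SCSNV_SITE" in out_lines[1]
        assert out_lines[3].split("\t")[7] == "."


class TestGeneModelReaders:
    def test_gtf_reader(self, toy_genome_files):
        models = read_gene_models(toy_genome_files["gtf"], "gtf")
        assert len(models) == 3
        for m in models:
            assert len(m.exons) == 3
            recs = enumerate_scsnvs([m], toy_genome_files["seq"])
            assert len(recs) == 126  # 2 introns

    def test_refflat_reader(self, tmp_path):
        # refFlat: txStart/exonStarts are 0-based half-open
        line = "g1\ttx1\tchr1\t+\t50\t290\t50\t290\t2\t50,230,\t110,290,\n"
        path = tmp_path / "genes.refflat"
        path.write_text(line)
        (m,) = read_gene_models(path, "refflat")
        assert m.exons == [(51, 110), (231, 290)]
        minus = "g2\ttx2\tchr1\t-\t50\t290\t50\t290\t2\t50,230,\t110,290,\n"
        path.write_text(minus)
        (m,) = read_gene_models(path, "refflat")
        assert m.exons == [(231, 290), (51, 110)]
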