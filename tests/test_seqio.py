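"""FASTA/GFF3 round trips, CDS translation and the six-frame ORF scanner."""

import numpy as np
import pytest

from matloci import seqio
from matloci.seqio import Contig, FastaFormatError, six_frame_orfs

from _oracles import brute_force_orfs


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestFasta:
    def test_read_basic_and_case_normalisation(self, tmp_path):
        p = _write(tmp_path, "a.fa", ">c1\nacgt\n>c2\nACGTN\n")
        contigs = seqio.read_fasta(p)
        assert [(c.id, c.sequence) for c in contigs] == [("c1", "ACGT"), ("c2", "ACGTN")]

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(tmp_path, "d.fa", ">c1\nACGT\n>c1\nGGGG\n")
        with pytest.raises(FastaFormatError, match="duplicate"):
            seqio.read_fasta(p)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(FastaFormatError, match="illegal"):
            Contig("x", "ACGU")

    def test_empty_sequence_rejected(self):
        with pytest.raises(FastaFormatError, match="empty"):
            Contig("x", "")

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        contigs = [
            Contig(f"c{i}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 400)))))
            for i in range(4)
        ]
        p = tmp_path / "rt.fa"
        seqio.write_fasta(contigs, p)
        back = seqio.read_fasta(p)
        assert [(c.id, c.sequence) for c in back] == [(c.id, c.sequence) for c in contigs]


class TestGff:
    def test_plus_and_minus_strand_translation(self, tmp_path):
        # single-exon CDS ATGAAATAA -> MK on both strands
        fwd = "TT" + "ATGAAATAA" + "TT"
        rev = "TT" + seqio.reverse_complement("ATGAAATAA") + "TT"
        fa = _write(tmp_path, "g.fa", f">f\n{fwd}\n>r\n{rev}\n")
        gff = _write(
            tmp_path,
            "g.gff3",
            "##gff-version 3\n"
            "f\tx\tgene\t3\t11\t.\t+\t.\tID=gf\n"
            "f\tx\tmRNA\t3\t11\t.\t+\t.\tID=gf.t;Parent=gf\n"
            "f\tx\tCDS\t3\t11\t.\t+\t0\tParent=gf.t\n"
            "r\tx\tgene\t3\t11\t.\t-\t.\tID=gr\n"
            "r\tx\tmRNA\t3\t11\t.\t-\t.\tID=gr.t;Parent=gr\n"
            "r\tx\tCDS\t3\t11\t.\t-\t0\tParent=gr.t\n",
        )
        models = seqio.read_gff(gff, seqio.read_fasta(fa))
        assert {m.gene_id: m.protein for m in models} == {"gf": "MK", "gr": "MK"}

    def test_two_cds_gene_has_one_intron(self, tmp_path):
        # ATG AAA | intron GTAG | TAA
        seq = "ATGAAA" + "GTAG" + "TAA"
        fa = _write(tmp_path, "i.fa", f">c\n{seq}\n")
        gff = _write(
            tmp_path,
            "i.gff3",
            "##gff-version 3\n"
            "c\tx\tgene\t1\t13\t.\t+\t.\tID=g\n"
            "c\tx\tmRNA\t1\t13\t.\t+\t.\tID=g.t;Parent=g\n"
            "c\tx\tCDS\t1\t6\t.\t+\t0\tParent=g.t\n"
            "c\tx\tCDS\t11\t13\t.\t+\t0\tParent=g.t\n",
        )
        (model,) = seqio.read_gff(gff, seqio.read_fasta(fa))
        assert model.intron_count == 1
        assert model.protein == "MK"

    def test_cds_not_multiple_of_three_rejected(self, tmp_path):
        fa = _write(tmp_path, "b.fa", ">c\nATGAAATAAT\n")
        gff = _write(
            tmp_path,
            "b.gff3",
            "##gff-version 3\nc\tx\tgene\t1\t10\t.\t+\t.\tID=g\n"
            "c\tx\tCDS\t1\t10\t.\t+\t0\tParent=g\n",
        )
        with pytest.raises(seqio.AnnotationError, match="divisible by 3"):
            seqio.read_gff(gff, seqio.read_fasta(fa))

    def test_gff_round_trip(self, tmp_path, dik_strain):
        contigs, models, _ = dik_strain
        p = tmp_path / "rt.gff3"
        seqio.write_gff(models, p)
        back = seqio.read_gff(p, contigs)
        orig = {m.gene_id: (m.strand, m.start, m.end, tuple(m.cds), m.protein) for m in models}
        rec = {m.gene_id: (m.strand, m.start, m.end, tuple(m.cds), m.protein) for m in back}
        assert rec == orig


class TestSixFrameOrfs:
    def test_forward_minimal(self):
        c = Contig("c", "TTATGAAATGATT")
        orfs = six_frame_orfs(c, min_aa=1, max_aa=10)
        fwd = [o for o in orfs if o.strand == "+"]
        assert any(o.peptide == "MK" and o.span == (2, 11) for o in fwd)

    def test_reverse_minimal(self):
        c = Contig("c", "TCATTTCAT")
        (orf,) = six_frame_orfs(c, min_aa=1, max_aa=5)
        assert orf.strand == "-" and orf.peptide == "MK"
        assert orf.end - orf.start == 3 * (len(orf.peptide) + 1)

    def test_window_edges_discard_not_clip(self):
        c = Contig("c", "AAATGAAATGAAAA")
        full = six_frame_orfs(c, (0, len(c)), 1, 10)
        clipped = six_frame_orfs(c, (4, len(c)), 1, 10)
        assert all(o.start >= 4 for o in clipped)
        assert len(clipped) < len(full) or all(o.start >= 4 for o in full)

    def test_empty_window(self):
        c = Contig("c", "ATGAAATGA")
        assert six_frame_orfs(c, (5, 5), 1, 10) == []

    def test_planted_orf_recovered_once(self):
        rng = np.random.default_rng(7)
        pep_nt = "ATG" + "GCT" * 49 + "TGA"  # 50-aa ORF
        left = "".join(rng.choice(list("ACGT"), size=500))
        right = "".join(rng.choice(list("ACGT"), size=500))
        c = Contig("c", left + "TTAATTAATTAA" + pep_nt + "TTAATTAATTAA" + right)
        orfs = [o for o in six_frame_orfs(c, min_aa=20, max_aa=100) if len(o.peptide) == 50]
        expect = brute_force_orfs(c.sequence, (0, len(c)), 20, 100, nested=False)
        assert {(o.strand, o.start, o.end, o.peptide) for o in orfs} <= expect
        assert sum(1 for o in orfs if o.peptide == "M" + "A" * 49) == 1

    @pytest.mark.parametrize("nested", [True, False])
    def test_matches_brute_force_on_random_sequences(self, nested):
        rng = np.random.default_rng(42)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            c = Contig("c", seq)
            got = {
                (o.strand, o.start, o.end, o.peptide)
                for o in six_frame_orfs(c, min_aa=5, max_aa=200, report_nested=nested)
            }
            want = brute_force_orfs(seq, (0, 2000), 5, 200, nested=nested)
            assert got == want

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        c = Contig("c", seq)
        rc = Contig("c", seqio.reverse_complement(seq))
        fwd = {
            (o.strand, o.start, o.end, o.peptide)
            for o in six_frame_orfs(c, min_aa=3, max_aa=300, report_nested=True)
        }
        n = len(seq)
        mirrored = {
            ("-" if s == "+" else "+", n - e, n - b, pep)
            for s, b, e, pep in (
                (o.strand, o.start, o.end, o.peptide)
                for o in six_frame_orfs(rc, min_aa=3, max_aa=300, report_nested=True)
            )
        }
        assert fwd == mirrored

    def test_invariants_on_output(self):
        c = Contig("c", "GG" + "ATG" + "AAA" * 30 + "TAA" + "GG")
        for o in six_frame_orfs(c, min_aa=1, max_aa=100):
            assert o.peptide.startswith("M")
            assert "*" not in o.peptide
            assert o.end - o.start == 3 * (len(o.peptide) + 1)
            assert 0 <= o.start < o.end <= len(c)
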