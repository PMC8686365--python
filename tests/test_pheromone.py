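"""CAAX/anchor rules, pheromone mining, receptor TM and intron QC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from matloci import pheromone, synthetic
from matloci.pheromone import (
    PheromoneParams,
    assemble_pr_locus,
    check_caax,
    find_acidic_anchor,
    hmm_hook,
    mine_pheromones,
    predict_tm_segments,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AA, min_size=4, max_size=60)


class TestCaax:
    def test_cvia_accepted_in_both_modes(self):
        pep = "M" + "G" * 40 + "CVIA"
        assert check_caax(pep, "strict").present
        assert check_caax(pep, "relaxed").present

    def test_ctis_relaxed_only(self):
        pep = "M" + "G" * 40 + "CTIS"
        assert not check_caax(pep, "strict").present
        assert check_caax(pep, "relaxed").present

    def test_avic_rejected(self):
        res = check_caax("M" + "G" * 40 + "AVIC")
        assert not res.present and res.reason == "C not at -4"

    def test_too_short(self):
        res = check_caax("MKC")
        assert not res.present and res.reason == "too short"

    def test_x_in_a_position_flagged_ambiguous(self):
        res = check_caax("M" + "G" * 40 + "CXIA")
        assert res.present and res.ambiguous

    @given(peptides)
    def test_strict_acceptance_implies_relaxed(self, pep):
        if check_caax(pep, "strict").present:
            assert check_caax(pep, "relaxed").present


class TestAcidicAnchor:
    def _pep(self, e_offsets, length=50):
        body = ["G"] * (length - 4)
        cys = length - 4
        for d in e_offsets:
            body[cys - d] = "E"
        return "".join(body) + "CVIA"

    def test_glu_at_ten(self):
        pep = self._pep([10])
        assert find_acidic_anchor(pep, check_caax(pep)) == 10

    def test_no_acid_in_window(self):
        pep = self._pep([])
        assert find_acidic_anchor(pep, check_caax(pep)) is None

    def test_smallest_in_window_offset_wins(self):
        pep = self._pep([9, 14])
        got = find_acidic_anchor(pep, check_caax(pep))
        # brute-force scan over all window offsets
        cys = len(pep) - 4
        want = min(d for d in range(8, 17) if pep[cys - d] == "E")
        assert got == want == 9

    def test_acid_outside_window_ignored(self):
        pep = self._pep([5, 20])
        assert find_acidic_anchor(pep, check_caax(pep)) is None

    def test_ed_mode(self):
        pep = self._pep([])
        pep = pep[: len(pep) - 4 - 12] + "D" + pep[len(pep) - 4 - 11 :]
        assert find_acidic_anchor(pep, check_caax(pep), acidic_mode="E") is None
        assert find_acidic_anchor(pep, check_caax(pep), acidic_mode="ED") == 12

    def test_requires_caax(self):
        with pytest.raises(ValueError):
            find_acidic_anchor("GGGG", check_caax("AAAA"))


class TestMining:
    def test_planted_precursors_accepted_decoys_rejected(self, mono_strain):
        contigs, models, truth = mono_strain
        pr_truth = next(h for h in truth["haplotypes"] if h["kind"] == "pr")
        contig = next(c for c in contigs if c.id == pr_truth["contig"])
        rec_ids = {r["gene_id"] for r in pr_truth["receptors"]}
        recs = [m for m in models if m.gene_id in rec_ids]
        calls = mine_pheromones(contig, recs)
        accepted = {(c.orf.strand, c.orf.start, c.orf.end) for c in calls if c.verdict == "accept"}
        assert accepted == {(p["strand"], p["start"], p["end"]) for p in pr_truth["pheromones"]}
        by_span = {(c.orf.strand, c.orf.start, c.orf.end): c for c in calls}
        for d in pr_truth["decoys"]:
            call = by_span[(d["strand"], d["start"], d["end"])]
            assert call.verdict == "reject"
            assert d["expected_reason"] in call.reject_reasons

    def test_accepts_satisfy_all_rules_post_hoc(self, mono_strain):
        contigs, models, truth = mono_strain
        pr_truth = next(h for h in truth["haplotypes"] if h["kind"] == "pr")
        contig = next(c for c in contigs if c.id == pr_truth["contig"])
        recs = [m for m in models if m.gene_id in {r["gene_id"] for r in pr_truth["receptors"]}]
        params = PheromoneParams()
        for c in mine_pheromones(contig, recs, params):
            if c.verdict != "accept":
                continue
            assert c.caax.present
            assert c.glu_offset is not None
            assert params.min_aa <= c.length_aa <= params.max_aa
            assert c.distance_nt <= params.window_nt

    def test_receptor_order_invariance(self, mono_strain):
        contigs, models, truth = mono_strain
        pr_truth = next(h for h in truth["haplotypes"] if h["kind"] == "pr")
        contig = next(c for c in contigs if c.id == pr_truth["contig"])
        recs = [m for m in models if m.gene_id in {r["gene_id"] for r in pr_truth["receptors"]}]
        a = mine_pheromones(contig, recs)
        b = mine_pheromones(contig, recs[::-1])
        key = lambda c: (c.orf.start, c.orf.end, c.verdict, tuple(c.reject_reasons))
        assert [key(c) for c in a] == [key(c) for c in b]

    def test_no_receptors_empty(self):
        from matloci.seqio import Contig

        assert mine_pheromones(Contig("c", "ACGT" * 100), []) == []


class TestHmmHook:
    def test_unconfigured_passthrough(self, mono_strain):
        calls = []
        assert hmm_hook(calls) is calls

    def test_stub_scorer_attaches_scores_without_changing_verdicts(self, mono_strain):
        contigs, models, truth = mono_strain
        pr_truth = next(h for h in truth["haplotypes"] if h["kind"] == "pr")
        contig = next(c for c in contigs if c.id == pr_truth["contig"])
        recs = [m for m in models if m.gene_id in {r["gene_id"] for r in pr_truth["receptors"]}]
        calls = mine_pheromones(contig, recs)
        before = [c.verdict for c in calls]
        out = hmm_hook(calls, scorer=lambda pep: 0.0)
        assert [c.profile_score for c in out] == [0.0] * len(out)
        assert [c.verdict for c in out] == before

    def test_empty_list(self):
        assert hmm_hook([], scorer=lambda p: 1.0) == []


class TestTmSegments:
    def _construct(self, n_tm):
        return "M" + "S" * 20 + ("L" * 21 + "S" * 10) * n_tm + "S" * 10

    @pytest.mark.parametrize("n", [0, 6, 7])
    def test_constructed_segment_counts(self, n):
        prot = "S" * 200 if n == 0 else self._construct(n)
        assert len(predict_tm_segments(prot)) == n

    def test_qc_tolerance(self):
        ok, n = pheromone.tm_qc(self._construct(6))
        assert ok and n == 6
        ok, n = pheromone.tm_qc(self._construct(4))
        assert not ok and n == 4

    def test_short_protein_empty(self):
        assert predict_tm_segments("MLLL") == []

    def test_synthetic_receptors_pass_7tm_qc(self, panel):
        for e in panel:
            if e.class_label.startswith("STE3"):
                ok, n = pheromone.tm_qc(e.protein)
                assert ok, (e.class_label, n)


class TestPrLocus:
    def test_assembled_locus_contents(self, dik_report):
        assert len(dik_report.pr_loci) == 2
        for locus in dik_report.pr_loci:
            assert sorted(lbl for _, lbl in locus.receptors) == [
                "STE3.1", "STE3.2", "STE3.3", "STE3.s1", "STE3.s2",
            ]
            assert len(locus.pheromones) == 3
            assert locus.warnings == []  # intron counts match the 5,5,4,4,5 pattern

    def test_wrong_intron_count_warns(self, mono_strain, panel):
        contigs, models, truth = mono_strain
        pr_truth = next(h for h in truth["haplotypes"] if h["kind"] == "pr")
        contig = next(c for c in contigs if c.id == pr_truth["contig"])
        recs = []
        for r in pr_truth["receptors"]:
            m = next(mm for mm in models if mm.gene_id == r["gene_id"])
            recs.append((m, r["class"]))
        # report a five-intron STE3.3 gene model
        ste33 = next(m for m, lbl in recs if lbl == "STE3.3")
        ste33.cds = ste33.cds + [(ste33.end - 3, ste33.end)]
        (locus,) = assemble_pr_locus(contig, recs, [])
        assert any("STE3.3" in w and "expected 4" in w for w in locus.warnings)

    def test_requires_receptor(self, mono_strain):
        contigs, _, _ = mono_strain
        with pytest.raises(ValueError):
            assemble_pr_locus(contigs[0], [], [])
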