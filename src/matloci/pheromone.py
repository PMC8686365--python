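"""P/R (MAT-B) locus mining: CAAX pheromone-precursor rules and receptor QC.

Basidiomycete lipopeptide pheromone precursors are short (tens of residues),
mature through farnesylation of a C-terminal CAAX motif (C = cysteine,
A = aliphatic, X = any residue) and carry a conserved acidic residue
(typically Glu) roughly 10 residues upstream of the CAAX cysteine. Candidate
precursors are mined as six-frame ORFs within a fixed window around STE3
pheromone-receptor homologs and accepted only if they satisfy all four
rules: CAAX present, acidic anchor in window, length in bounds, and
proximity to a receptor.

Receptors themselves are QC'd two ways: a Kyte-Doolittle hydropathy scan
should find about seven transmembrane segments (STE3 proteins are 7-TM
GPCRs), and gene models should carry the expected intron counts
(5 for STE3.1/STE3.2/STE3.s2, 4 for STE3.3/STE3.s1).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .seqio import Contig, GeneModel, Orf, six_frame_orfs

__all__ = [
    "CaaxResult",
    "PheromoneCall",
    "PheromoneParams",
    "PRLocus",
    "check_caax",
    "find_acidic_anchor",
    "mine_pheromones",
    "hmm_hook",
    "predict_tm_segments",
    "assemble_pr_locus",
    "EXPECTED_INTRONS",
    "ALIPHATIC_STRICT",
    "ALIPHATIC_RELAXED",
]

log = logging.getLogger(__name__)

ALIPHATIC_STRICT = frozenset("AVLI")
ALIPHATIC_RELAXED = frozenset("AVLIMTSCGF")

EXPECTED_INTRONS = {"STE3.1": 5, "STE3.2": 5, "STE3.3": 4, "STE3.s1": 4, "STE3.s2": 5}

# Kyte-Doolittle hydropathy scale
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class CaaxResult:
    present: bool
    mode: str
    cys_index: int | None = None  # position of C counted from the C-terminus (4)
    a1: str | None = None
    a2: str | None = None
    x: str | None = None
    ambiguous: bool = False  # an X residue occupied a constrained position
    reason: str | None = None


@dataclass(frozen=True)
class PheromoneParams:
    """Tunable thresholds of the pheromone-precursor search."""

    window_nt: int = 5000          # scan distance either side of a receptor gene
    min_aa: int = 20               # precursor length bounds (mature peptide, aa)
    max_aa: int = 100
    caax_mode: str = "relaxed"     # 'strict' {AVLI} or 'relaxed' aliphatic set
    acidic_window: tuple[int, int] = (8, 16)  # anchor offsets upstream of the CAAX Cys
    acidic_mode: str = "E"         # 'E' (Glu only) or 'ED' (Glu or Asp)
    scan_slack_nt: int = 2500      # extra margin scanned so near-misses get a verdict
    report_nested: bool = False


@dataclass
class PheromoneCall:
    orf: Orf
    caax: CaaxResult
    glu_offset: int | None
    length_aa: int
    anchor_receptor_id: str
    distance_nt: int
    verdict: str = "reject"        # 'accept' | 'reject'
    reject_reasons: list[str] = field(default_factory=list)
    profile_score: float | None = None


@dataclass
class PRLocus:
    contig_id: str
    start: int
    end: int
    receptors: list[tuple[str, str]]          # (gene_id, STE3 class label)
    pheromones: list[PheromoneCall]
    other_genes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def check_caax(peptide: str, mode: str = "relaxed") -> CaaxResult:
    """Test the C-terminal CAAX prenylation motif.

    Present iff the residue four from the end is Cys and both A positions are
    in the mode's aliphatic set (strict: A/V/L/I; relaxed additionally allows
    M/T/S/C/G/F, needed for motifs like CTIS). X residues at constrained
    positions leave the motif present but flagged ambiguous.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown CAAX mode {mode!r}")
    if len(peptide) < 4:
        return CaaxResult(False, mode, reason="too short")
    c, a1, a2, x = peptide[-4], peptide[-3], peptide[-2], peptide[-1]
    if c != "C":
        return CaaxResult(False, mode, a1=a1, a2=a2, x=x, reason="C not at -4")
    allowed = ALIPHATIC_STRICT if mode == "strict" else ALIPHATIC_RELAXED
    ambiguous = "X" in (a1, a2)
    ok = all(r in allowed or r == "X" for r in (a1, a2))
    if not ok:
        return CaaxResult(False, mode, 4, a1, a2, x, reason="non-aliphatic A position")
    return CaaxResult(True, mode, 4, a1, a2, x, ambiguous=ambiguous)


def find_acidic_anchor(
    peptide: str,
    caax: CaaxResult,
    window: tuple[int, int] = (8, 16),
    acidic_mode: str = "E",
) -> int | None:
    """Smallest in-window offset of an acidic residue upstream of the CAAX Cys.

    Offset d means the residue d positions before the cysteine (the Cys sits
    at index len-4). Offsets reaching past the N-terminus are clipped.
    """
    if not caax.present:
        raise ValueError("acidic anchor search requires a present CAAX motif")
    acidic = {"E"} if acidic_mode == "E" else {"E", "D"}
    cys = len(peptide) - 4
    lo, hi = window
    for d in range(lo, hi + 1):
        idx = cys - d
        if idx < 0:
            break
        if peptide[idx] in acidic:
            return d
    return None


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Nucleotide gap between two intervals (0 when they touch or overlap)."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def evaluate_orf(
    orf: Orf, receptor: GeneModel, params: PheromoneParams
) -> PheromoneCall:
    """Apply the four precursor rules to one ORF anchored at one receptor."""
    caax = check_caax(orf.peptide, params.caax_mode)
    glu = (
        find_acidic_anchor(orf.peptide, caax, params.acidic_window, params.acidic_mode)
        if caax.present
        else None
    )
    dist = _gap(orf.span, receptor.span)
    reasons = []
    if not caax.present:
        reasons.append("no CAAX")
    elif glu is None:
        reasons.append("no acidic anchor")
    if len(orf.peptide) < params.min_aa:
        reasons.append("too short")
    elif len(orf.peptide) > params.max_aa:
        reasons.append("too long")
    if dist > params.window_nt:
        reasons.append("outside window")
    return PheromoneCall(
        orf=orf,
        caax=caax,
        glu_offset=glu,
        length_aa=len(orf.peptide),
        anchor_receptor_id=receptor.gene_id,
        distance_nt=dist,
        verdict="reject" if reasons else "accept",
        reject_reasons=reasons,
    )


def mine_pheromones(
    contig: Contig,
    receptor_genes: list[GeneModel],
    params: PheromoneParams = PheromoneParams(),
) -> list[PheromoneCall]:
    """Scan around each receptor for precursor ORFs and rule on every candidate.

    The scan region extends ``window_nt + scan_slack_nt`` either side of each
    receptor so that ORFs just outside the window are reported with an
    "outside window" rejection instead of silently dropped. ORFs seen from
    several receptor windows are deduplicated, keeping the nearest receptor
    as anchor; output is sorted by coordinate and independent of receptor
    list order.
    """
    if not receptor_genes:
        log.warning("mine_pheromones: no receptor genes on %s", contig.id)
        return []
    reach = params.window_nt + params.scan_slack_nt
    # scan with permissive length bounds so too-short/too-long candidates
    # still receive a verdict with a reason
    scan_min = max(4, params.min_aa // 2)
    scan_max = max(params.max_aa * 2, params.max_aa + 50)
    best: dict[tuple, PheromoneCall] = {}
    for rec in sorted(receptor_genes, key=lambda m: (m.start, m.gene_id)):
        window = (rec.start - reach, rec.end + reach)
        for orf in six_frame_orfs(contig, window, scan_min, scan_max, params.report_nested):
            call = evaluate_orf(orf, rec, params)
            key = (orf.strand, orf.start, orf.end)
            prev = best.get(key)
            if prev is None or call.distance_nt < prev.distance_nt:
                best[key] = call
    return sorted(best.values(), key=lambda c: (c.orf.start, c.orf.strand))


def hmm_hook(calls, scorer=None, profile_path: str | None = None):
    """Optionally attach PF08015-family profile scores to calls.

    ``scorer`` may be a callable peptide -> score. If absent and
    ``profile_path`` points at an HMM file, pyhmmer is tried. Scores are
    advisory: verdicts never change, and any failure degrades to a logged
    skip. With neither configured the calls pass through unmodified.
    """
    if scorer is None and profile_path is None:
        return calls
    if scorer is None:
        try:
            scorer = _pyhmmer_scorer(profile_path)
        except Exception as exc:  # missing pyhmmer/profile: advisory only
            log.warning("profile scoring unavailable (%s); skipping", exc)
            return calls
    for call in calls:
        try:
            call.profile_score = float(scorer(call.orf.peptide))
        except Exception as exc:
            log.warning("profile scorer failed on %s: %s", call.orf, exc)
    return calls


def _pyhmmer_scorer(profile_path: str):
    import pyhmmer

    with pyhmmer.plan7.HMMFile(profile_path) as fh:
        hmm = fh.read()
    alphabet = hmm.alphabet
    pipeline = pyhmmer.plan7.Pipeline(alphabet)

    def score(peptide: str) -> float:
        seq = pyhmmer.easel.TextSequence(name=b"q", sequence=peptide).digitize(alphabet)
        hits = pipeline.search_hmm(hmm, pyhmmer.easel.DigitalSequenceBlock(alphabet, [seq]))
        return hits[0].score if len(hits) else 0.0

    return score


def predict_tm_segments(
    protein: str, kd_window: int = 19, threshold: float = 1.6, merge_gap: int = 5
) -> list[tuple[int, int]]:
    """Transmembrane segments from a sliding Kyte-Doolittle hydropathy mean.

    Returns maximal residue intervals whose window-mean hydropathy exceeds
    ``threshold``; runs separated by fewer than ``merge_gap`` window starts
    are merged. Proteins shorter than the window give an empty list.
    """
    n = len(protein)
    if n < kd_window:
        return []
    values = np.array([KD_SCALE.get(a, 0.0) for a in protein])
    means = np.convolve(values, np.ones(kd_window) / kd_window, mode="valid")
    hot = means > threshold
    segments: list[list[int]] = []
    for i, flag in enumerate(hot):
        if not flag:
            continue
        if segments and i - segments[-1][1] < merge_gap:
            segments[-1][1] = i
        else:
            segments.append([i, i])
    return [(s, e + kd_window) for s, e in segments]


def tm_qc(protein: str, expected: int = 7, tolerance: int = 1, **kw) -> tuple[bool, int]:
    """Receptor 7-TM sanity check: pass iff |segments - expected| <= tolerance."""
    n = len(predict_tm_segments(protein, **kw))
    return abs(n - expected) <= tolerance, n


def assemble_pr_locus(
    contig: Contig,
    receptors: list[tuple[GeneModel, str]],
    accepted_calls: list[PheromoneCall],
    other_genes: list[GeneModel] | None = None,
) -> list[PRLocus]:
    """Bundle receptors + accepted pheromone calls into per-contig P/R loci.

    Intron counts of receptor gene models are compared with the expected
    5/5/4/4/5 pattern (STE3.1, STE3.2, STE3.3, STE3.s1, STE3.s2); deviations
    are warnings, not errors — the native population contains known
    five-intron STE3.3 haplotypes.
    """
    if not receptors:
        raise ValueError("assemble_pr_locus requires at least one receptor")
    per_contig: dict[str, list[tuple[GeneModel, str]]] = {}
    for m, lbl in receptors:
        per_contig.setdefault(m.contig_id, []).append((m, lbl))
    loci = []
    for contig_id, recs in sorted(per_contig.items()):
        calls = [c for c in accepted_calls if c.orf.contig_id == contig_id]
        others = [g for g in (other_genes or []) if g.contig_id == contig_id]
        coords = (
            [m.start for m, _ in recs] + [m.end for m, _ in recs]
            + [c.orf.start for c in calls] + [c.orf.end for c in calls]
            + [g.start for g in others] + [g.end for g in others]
        )
        warnings = []
        seen: dict[str, int] = {}
        for m, lbl in recs:
            seen[lbl] = seen.get(lbl, 0) + 1
            expect = EXPECTED_INTRONS.get(lbl)
            if expect is not None and m.intron_count != expect:
                warnings.append(
                    f"{m.gene_id} ({lbl}): {m.intron_count} introns, expected {expect}"
                )
        for lbl, n in seen.items():
            if n > 1:
                warnings.append(f"receptor class {lbl} appears {n} times on {contig_id}")
        loci.append(
            PRLocus(
                contig_id,
                min(coords),
                max(coords),
                [(m.gene_id, lbl) for m, lbl in sorted(recs, key=lambda t: t[0].start)],
                sorted(calls, key=lambda c: c.orf.start),
                [g.gene_id for g in sorted(others, key=lambda g: g.start)],
                warnings,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Reports


def write_pheromone_gff(calls, path: str | os.PathLike) -> None:
    """GFF3 of accepted calls (feature type pheromone_precursor)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(c for c in calls if c.verdict == "accept"):
            motif = c.orf.peptide[-4:]
            fh.write(
                f"{c.orf.contig_id}\tmatloci\tpheromone_precursor\t{c.orf.start + 1}\t{c.orf.end}"
                f"\t.\t{c.orf.strand}\t0\tID=phb{i + 1};anchor_receptor={c.anchor_receptor_id};"
                f"caax={motif};glu_offset={c.glu_offset}\n"
            )


def write_rejection_table(calls, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tlength_aa\tanchor\tdistance_nt\treasons\n")
        for c in calls:
            if c.verdict == "accept":
                continue
            fh.write(
                f"{c.orf.contig_id}\t{c.orf.start}\t{c.orf.end}\t{c.orf.strand}\t"
                f"{c.length_aa}\t{c.anchor_receptor_id}\t{c.distance_nt}\t"
                f"{';'.join(c.reject_reasons)}\n"
            )
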