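"""Protein classification against a reference panel by Smith-Waterman alignment.

Replaces a BLASTP search: the panel is small (a dozen mating-type reference
proteins), so every query is aligned against every panel entry with full
local alignment (BLOSUM62, gap open 11, extend 1) and the best hit passing
identity/coverage thresholds is reported. Class labels come from a closed
vocabulary: the two HD-locus flanking markers (Mip, Bfg), five homeodomain
gene classes and five STE3 receptor classes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "CLASS_LABELS",
    "PanelEntry",
    "ReferencePanel",
    "HomologyHit",
    "best_hit",
    "annotate_genome",
    "load_panel",
    "write_panel",
    "write_hit_table",
]

CLASS_LABELS = (
    "Mip",
    "Bfg",
    "HD1.1",
    "HD1.2",
    "HD1.3",
    "HD2.1",
    "HD2.2",
    "STE3.1",
    "STE3.2",
    "STE3.3",
    "STE3.s1",
    "STE3.s2",
)

HD_LABELS = ("HD1.1", "HD2.1", "HD1.2", "HD1.3", "HD2.2")
STE3_LABELS = ("STE3.1", "STE3.2", "STE3.3", "STE3.s1", "STE3.s2")

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 0.5


class PanelError(ValueError):
    """Raised for empty panels or labels outside the closed vocabulary."""


@dataclass(frozen=True)
class PanelEntry:
    class_label: str
    protein: str
    source: str = ""

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise PanelError(f"unknown class label {self.class_label!r}")
        if not self.protein:
            raise PanelError(f"{self.class_label}: empty reference protein")


@dataclass
class ReferencePanel:
    entries: list[PanelEntry]

    def __post_init__(self):
        if not self.entries:
            raise PanelError("reference panel is empty")

    def labels(self) -> set[str]:
        return {e.class_label for e in self.entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class HomologyHit:
    query_gene_id: str
    class_label: str
    identity: float  # percent identity over aligned columns (gaps included)
    score: float
    coverage: float  # fraction of the reference covered by the local alignment


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def _align_stats(ref: str, query: str) -> tuple[float, float, float]:
    """(score, percent identity, reference coverage) of the best local alignment."""
    try:
        aln = _ALIGNER.align(ref, query)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0, 0.0
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    ref_blocks = aln.aligned[0]
    covered = int(sum(e - s for s, e in ref_blocks))
    return float(aln.score), identity, covered / len(ref)


def best_hit(
    protein: str,
    panel: ReferencePanel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    gene_id: str = "",
) -> HomologyHit | None:
    """Best-scoring panel hit passing both thresholds, or None.

    Ties on score are broken by higher identity, then lexicographic class
    label, so classification is deterministic and independent of panel order.
    """
    if not protein:
        raise ValueError("empty query protein")
    if not (0 <= min_identity <= 100) or not (0 <= min_coverage <= 1):
        raise ValueError("thresholds out of range")
    best: tuple[float, float, str, float] | None = None
    for entry in panel:
        score, identity, coverage = _align_stats(entry.protein, protein)
        if identity < min_identity or coverage < min_coverage:
            continue
        cand = (score, identity, entry.class_label, coverage)
        if best is None or _beats(cand, best):
            best = cand
    if best is None:
        return None
    return HomologyHit(gene_id, best[2], round(best[1], 3), best[0], round(best[3], 4))


def _beats(a, b) -> bool:
    """Higher score, then higher identity, then lexicographically smaller label."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] > b[1]
    return a[2] < b[2]


def annotate_genome(
    models,
    panel: ReferencePanel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, HomologyHit]:
    """Classify every gene model with a protein; genes with no hit are absent."""
    hits: dict[str, HomologyHit] = {}
    for m in models:
        if not m.protein:
            continue
        h = best_hit(m.protein, panel, min_identity, min_coverage, gene_id=m.gene_id)
        if h is not None:
            hits[m.gene_id] = h
    return hits


def load_panel(path: str | os.PathLike) -> ReferencePanel:
    """Load a panel FASTA whose headers are ``class_label|free text``."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label, _, source = rec.description.partition("|")
        entries.append(PanelEntry(label.strip(), str(rec.seq).upper(), source.strip()))
    return ReferencePanel(entries)


def write_panel(panel: ReferencePanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for e in panel:
            fh.write(f">{e.class_label}|{e.source}\n")
            for i in range(0, len(e.protein), 60):
                fh.write(e.protein[i : i + 60] + "\n")


def write_hit_table(hits: dict[str, HomologyHit], path: str | os.PathLike) -> None:
    """TSV hit report: gene_id, label, identity, coverage, score."""
    with open(path, "w") as fh:
        fh.write("gene_id\tclass_label\tidentity\tcoverage\tscore\n")
        for gid in sorted(hits):
            h = hits[gid]
            fh.write(f"{gid}\t{h.class_label}\t{h.identity:.2f}\t{h.coverage:.3f}\t{h.score:.1f}\n")
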