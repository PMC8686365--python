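"""Sequence and annotation I/O plus translation/ORF primitives.

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from the
standard's 1-based inclusive convention. Translation uses the standard
genetic code (NCBI table 1); codons containing N translate to X.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Contig",
    "GeneModel",
    "Orf",
    "FastaFormatError",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "translate_cds",
    "reverse_complement",
    "six_frame_orfs",
]

_DNA_OK = set("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty sequence, duplicate id, bad alphabet)."""


class AnnotationError(ValueError):
    """Raised for inconsistent gene annotations (bad CDS length, out-of-bounds features)."""


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence over {A,C,G,T,N}, stored upper-case."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise FastaFormatError(f"contig {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_OK
        if bad:
            raise FastaFormatError(
                f"contig {self.id!r}: illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One annotated gene: spliced CDS intervals and the translated protein.

    ``exons`` and ``cds`` are lists of 0-based half-open (start, end) tuples in
    contig coordinates, sorted ascending and non-overlapping regardless of
    strand. On the minus strand the spliced CDS is reverse-complemented before
    translation.
    """

    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    protein: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def intron_count(self) -> int:
        """Introns between consecutive CDS intervals (used for receptor QC)."""
        return max(0, len(self.cds) - 1)

    def spliced_cds(self, contig: Contig) -> str:
        seq = "".join(contig.sequence[s:e] for s, e in self.cds)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass(frozen=True)
class Orf:
    """An open reading frame (ATG..stop) located on the forward-strand axis.

    ``span`` covers start codon through stop codon inclusive, so
    ``end - start == 3 * (len(peptide) + 1)``. ``frame`` is the codon phase on
    the reading strand.
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    peptide: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code). N-containing codons yield X.

    The trailing stop codon, if present, is stripped from the peptide.
    """
    if len(cds) % 3 != 0:
        raise AnnotationError(f"CDS length {len(cds)} not divisible by 3")
    prot = str(Seq(cds).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a (multi-)FASTA into Contig records, order preserved.

    Lower-case input is normalised to upper case; duplicate ids and empty
    sequences are rejected.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, str(rec.seq)))
    if not contigs:
        # distinguish empty/garbage files from a valid empty parse
        with open(path) as fh:
            head = fh.read(1)
        if head != ">":
            raise FastaFormatError(f"{path}: not FASTA (first character {head!r})")
    return contigs


def write_fasta(contigs, path: str | os.PathLike, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), wrap):
                fh.write(c.sequence[i : i + wrap] + "\n")


def write_protein_fasta(models, path: str | os.PathLike, wrap: int = 60) -> None:
    """Write the translations of gene models as protein FASTA."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.gene_id}\n")
            for i in range(0, len(m.protein), wrap):
                fh.write(m.protein[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | os.PathLike, contigs) -> list[GeneModel]:
    """Parse a GFF3 file (gene/mRNA/exon/CDS) into GeneModel records.

    Proteins are computed from the spliced CDS; minus-strand genes are
    translated from the reverse complement. Raises :class:`AnnotationError`
    for CDS not divisible by 3 or features outside their contig.
    """
    by_id = {c.id: c for c in contigs}
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        contig = by_id.get(gene.seqid)
        if contig is None:
            raise AnnotationError(f"gene {gene.id}: unknown contig {gene.seqid!r}")
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        for feat in db.children(gene.id, featuretype=("exon", "CDS"), order_by="start"):
            iv = (feat.start - 1, feat.end)  # 1-based inclusive -> 0-based half-open
            if iv[0] < 0 or iv[1] > len(contig):
                raise AnnotationError(
                    f"gene {gene.id}: feature {iv} outside contig {contig.id} (len {len(contig)})"
                )
            (exons if feat.featuretype == "exon" else cds).append(iv)
        exons.sort()
        cds.sort()
        if not exons and cds:
            exons = list(cds)
        total = sum(e - s for s, e in cds)
        if total % 3 != 0:
            raise AnnotationError(f"gene {gene.id}: CDS length {total} not divisible by 3")
        model = GeneModel(
            gene_id=gene.id,
            contig_id=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
            exons=exons,
            cds=cds,
        )
        if cds:
            model.protein = translate_cds(model.spliced_cds(contig))
        models.append(model)
    return models


def write_gff(models, path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS with ID/Parent)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g = m.gene_id
            fh.write(
                f"{m.contig_id}\tmatloci\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\tID={g}\n"
            )
            fh.write(
                f"{m.contig_id}\tmatloci\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={g}.t1;Parent={g}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.contig_id}\tmatloci\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={g}.t1\n"
                )
            for i, (s, e) in enumerate(m.cds):
                fh.write(
                    f"{m.contig_id}\tmatloci\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={g}.cds{i};Parent={g}.t1\n"
                )


# ---------------------------------------------------------------------------
# Six-frame ORF scan


def _scan_strand(seq: str, min_aa: int, max_aa: int, report_nested: bool):
    """Yield (frame, start, end, peptide) ORFs on the given (already oriented) strand.

    ORFs require an ATG start and an in-frame TAA/TAG/TGA stop, both inside the
    sequence. Per stop codon, only the most 5' ATG is reported unless
    ``report_nested`` is set.
    """
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if starts:
                    use = starts if report_nested else starts[:1]
                    for s in use:
                        aa_len = (pos - s) // 3
                        if min_aa <= aa_len <= max_aa:
                            pep = translate_cds(seq[s:pos])
                            yield (frame, s, pos + 3, pep)
                starts = []
            elif codon == START_CODON:
                starts.append(pos)


def six_frame_orfs(
    contig: Contig,
    window: tuple[int, int] | None = None,
    min_aa: int = 1,
    max_aa: int = 10**9,
    report_nested: bool = False,
) -> list[Orf]:
    """Find every ATG..stop ORF fully inside ``window`` in all six frames.

    The window is clipped to contig bounds; ORFs overlapping a window edge are
    discarded, not clipped. Coordinates in the returned :class:`Orf` records
    are on the forward strand regardless of the ORF's strand. Results are
    sorted by (start, strand, frame).
    """
    if min_aa < 1 or min_aa > max_aa:
        raise ValueError("require 1 <= min_aa <= max_aa")
    start, end = window if window is not None else (0, len(contig))
    start = max(0, start)
    end = min(len(contig), end)
    if end - start < 6:
        return []
    sub = contig.sequence[start:end]
    out: list[Orf] = []
    for frame, s, e, pep in _scan_strand(sub, min_aa, max_aa, report_nested):
        out.append(Orf(contig.id, "+", frame, start + s, start + e, pep))
    rc = reverse_complement(sub)
    m = len(sub)
    for frame, s, e, pep in _scan_strand(rc, min_aa, max_aa, report_nested):
        # map reverse-strand coordinates back onto the forward axis
        out.append(Orf(contig.id, "-", frame, start + m - e, start + m - s, pep))
    out.sort(key=lambda o: (o.start, o.strand, o.frame))
    return out
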