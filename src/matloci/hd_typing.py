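"""HD (MAT-A) locus location, four-type haplotyping and population counts.

The HD locus of *Hypsizygus marmoreus* sits between two conserved flanking
markers, the mitochondrial intermediate peptidase gene (Mip) and the beta
flanking gene (Bfg). Between them lie up to five homeodomain transcription
factor genes; three (HD1.1, HD1.2, HD2.2) are conserved in every haplotype
while HD2.1 and HD1.3 are variably absent, giving four gene-content classes:

    Type 1: HD1.1, HD2.1, HD1.2, HD1.3, HD2.2
    Type 2: HD1.1,        HD1.2, HD1.3, HD2.2   (HD2.1 absent)
    Type 3: HD1.1, HD2.1, HD1.2,        HD2.2   (HD1.3 absent)
    Type 4: HD1.1,        HD1.2,        HD2.2   (both absent)
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .homology import HD_LABELS, HomologyHit

__all__ = [
    "HDLocus",
    "HAPLOTYPE_TYPES",
    "CORE_CLASSES",
    "NonCanonicalHaplotypeError",
    "locate_hd_loci",
    "type_haplotype",
    "count_type_pairs",
    "load_table1",
    "write_locus_report",
]

HAPLOTYPE_TYPES = ("Type1", "Type2", "Type3", "Type4")
CORE_CLASSES = frozenset({"HD1.1", "HD1.2", "HD2.2"})
CANONICAL_ORDER = ("HD1.1", "HD2.1", "HD1.2", "HD1.3", "HD2.2")

# presence/absence of the two dispensable classes -> Type
_TYPE_TABLE = {
    (True, True): "Type1",   # HD2.1 present, HD1.3 present
    (False, True): "Type2",  # HD2.1 absent
    (True, False): "Type3",  # HD1.3 absent
    (False, False): "Type4",
}

DEFAULT_MAX_SPAN_NT = 100_000


class NonCanonicalHaplotypeError(ValueError):
    """A locus missing one of the conserved core genes HD1.1/HD1.2/HD2.2."""


@dataclass
class HDLocus:
    """The Mip..Bfg interval with its ordered, classified HD genes.

    ``genes`` is ordered by coordinate starting from the Mip side. A locus
    with only one flanking marker found is returned with ``complete=False``.
    """

    contig_id: str
    start: int
    end: int
    genes: list[tuple[str, str, str]]  # (gene_id, class_label, strand), Mip side first
    mip_gene_id: str | None
    bfg_gene_id: str | None
    complete: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def class_set(self) -> frozenset:
        return frozenset(lbl for _, lbl, _ in self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [gid for gid, _, _ in self.genes]


def locate_hd_loci(models, hits: dict[str, HomologyHit], max_span_nt: int = DEFAULT_MAX_SPAN_NT):
    """Anchor HD loci on Mip/Bfg flag-gene pairs, one locus per contig.

    For every contig carrying both a Mip and a Bfg hit within ``max_span_nt``,
    an :class:`HDLocus` is emitted containing all HD-classified genes between
    them, ordered from the Mip side. Contigs with only one marker yield
    incomplete-locus records. More than two complete loci for one strain is
    reported as a warning on each locus (suspicious assembly).
    """
    by_id = {m.gene_id: m for m in models}
    by_contig: dict[str, dict[str, list]] = {}
    for gid, hit in hits.items():
        m = by_id.get(gid)
        if m is None:
            continue
        slot = by_contig.setdefault(m.contig_id, {"Mip": [], "Bfg": [], "HD": []})
        if hit.class_label == "Mip":
            slot["Mip"].append(m)
        elif hit.class_label == "Bfg":
            slot["Bfg"].append(m)
        elif hit.class_label in HD_LABELS:
            slot["HD"].append((m, hit.class_label))

    loci: list[HDLocus] = []
    for contig_id, slot in sorted(by_contig.items()):
        mips, bfgs = slot["Mip"], slot["Bfg"]
        if mips and bfgs:
            mip = min(mips, key=lambda m: m.start)
            bfg = min(bfgs, key=lambda m: abs(m.start - mip.start))
            span = (min(mip.start, bfg.start), max(mip.end, bfg.end))
            if span[1] - span[0] > max_span_nt:
                locus = HDLocus(contig_id, mip.start, mip.end, [], mip.gene_id, None, False,
                                [f"Bfg found but {span[1] - span[0]} nt from Mip (> {max_span_nt})"])
                loci.append(locus)
                continue
            inside = [
                (m, lbl) for m, lbl in slot["HD"] if span[0] <= m.start and m.end <= span[1]
            ]
            mip_first = mip.start <= bfg.start
            inside.sort(key=lambda t: t[0].start, reverse=not mip_first)
            genes = [(m.gene_id, lbl, m.strand) for m, lbl in inside]
            warnings = []
            seen = Counter(lbl for _, lbl, _ in genes)
            for lbl, n in seen.items():
                if n > 1:
                    warnings.append(f"class {lbl} appears {n} times in one haplotype")
            if genes and genes[0][1] != "HD1.1":
                warnings.append(
                    f"Mip-adjacent gene is {genes[0][1]}, expected HD1.1 next to Mip"
                )
            loci.append(
                HDLocus(contig_id, span[0], span[1], genes, mip.gene_id, bfg.gene_id,
                        True, warnings)
            )
        elif mips or bfgs:
            m = (mips or bfgs)[0]
            which = "Mip" if mips else "Bfg"
            loci.append(
                HDLocus(contig_id, m.start, m.end, [], m.gene_id if mips else None,
                        m.gene_id if bfgs else None, False,
                        [f"incomplete locus: only {which} found on {contig_id}"])
            )
    complete = [l for l in loci if l.complete]
    if len(complete) > 2:
        for l in complete:
            l.warnings.append(f"{len(complete)} complete HD loci in one strain: suspicious assembly")
    return loci


def type_haplotype(locus_or_classes) -> str:
    """Assign Type1..Type4 from presence/absence of HD2.1 and HD1.3.

    Accepts an :class:`HDLocus` or any iterable of class labels. Raises
    :class:`NonCanonicalHaplotypeError` when a conserved core gene
    (HD1.1, HD1.2 or HD2.2) is missing; gene order never affects the result.
    """
    if isinstance(locus_or_classes, HDLocus):
        classes = set(locus_or_classes.class_set)
    else:
        classes = set(locus_or_classes)
    missing_core = CORE_CLASSES - classes
    if missing_core:
        raise NonCanonicalHaplotypeError(
            f"missing conserved core gene(s) {sorted(missing_core)}; "
            "only HD2.1/HD1.3 may be absent"
        )
    return _TYPE_TABLE[("HD2.1" in classes, "HD1.3" in classes)]


def count_type_pairs(table: pd.DataFrame) -> dict[tuple, int]:
    """Group a strain population by unordered haplotype-type pair.

    ``table`` needs columns strain_id, karyotype ('mono'|'di'), type_a and
    (for dikaryons) type_b. Dikaryons are keyed by the sorted type pair
    (same-type pairs allowed); monokaryons by a 1-tuple. Group totals over
    pairs always sum to the number of dikaryon rows.
    """
    counts: Counter = Counter()
    for row in table.itertuples(index=False):
        if row.karyotype == "di":
            pair = tuple(sorted((row.type_a, row.type_b)))
            if len(pair) != 2 or not all(pair):
                raise ValueError(f"dikaryon row {row.strain_id} needs two types")
            counts[pair] += 1
        elif row.karyotype == "mono":
            counts[(row.type_a,)] += 1
        else:
            raise ValueError(f"unknown karyotype {row.karyotype!r}")
    return dict(counts)


def load_table1() -> pd.DataFrame:
    """The packaged dikaryotic strain roster (strain id + two haplotype types)."""
    with resources.files("matloci.data").joinpath("table1_strains.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def write_locus_report(loci, path: str | os.PathLike) -> None:
    payload = []
    for l in loci:
        try:
            htype = type_haplotype(l) if l.complete else None
        except NonCanonicalHaplotypeError as exc:
            htype = f"non-canonical ({exc})"
        payload.append(
            {
                "contig": l.contig_id,
                "start": l.start,
                "end": l.end,
                "complete": l.complete,
                "mip": l.mip_gene_id,
                "bfg": l.bfg_gene_id,
                "genes": [{"id": g, "class": c, "strand": s} for g, c, s in l.genes],
                "type": htype,
                "warnings": l.warnings,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
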