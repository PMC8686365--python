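"""Synthetic strain-genome generator with machine-readable truth tables.

Emits monokaryon/dikaryon genomes (FASTA + GFF3) carrying planted HD and P/R
mating-type loci so the whole pipeline is testable without downloading any
assembly:

* HD haplotypes: one contig with Mip, the Type's HD genes in canonical order
  (HD1.1, HD2.1, HD1.2, HD1.3, HD2.2, absent classes removed, neighbouring
  HD1/HD2 pairs divergently transcribed), then Bfg; spacers 200-2000 nt.
* P/R haplotypes: a ~22 kb contig with the five receptor genes (intron
  counts 5,5,4,4,5 for STE3.1/STE3.2/STE3.3/STE3.s1/STE3.s2 — i.e. four for
  STE3.3 and STE3.s1), three pheromone-precursor ORFs (PHB1/PHB3 ending
  CVIA, PHB2 ending CTIS, ~50 aa, Glu 10 residues upstream of the CAAX Cys,
  PHB3 and PHB2 flanking STE3.3), three hypothetical-protein genes and
  rule-violating decoy ORFs.

Coding sequences are random-codon realisations of a deterministic synthetic
reference panel (not real database sequences); alleles of the same class
differ by seeded nucleotide mutations, so allele fingerprints differ while
panel classification stays unambiguous. All output is bit-reproducible for
a fixed seed.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .hd_typing import CANONICAL_ORDER, load_table1
from .homology import PanelEntry, ReferencePanel
from .mating import allele_fingerprint
from .pheromone import PheromoneParams, mine_pheromones
from .seqio import Contig, GeneModel, reverse_complement, translate_cds, write_fasta, write_gff

__all__ = [
    "PANEL_SEED",
    "StrainSpec",
    "build_default_panel",
    "allele_cds",
    "generate_hd_haplotype",
    "generate_pr_haplotype",
    "generate_strain",
    "generate_population",
    "random_specs",
    "table1_specs",
]

PANEL_SEED = 20_2083  # master seed of the packaged synthetic panel

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "AVLIFMC"
_HYDROPHILIC = "STNQDEKRGPHY"

# stops every reading frame on both strands (own reverse complement)
_INSULATOR = "TTAATTAATTAA"

_HD_STRANDS = {"HD1.1": "-", "HD2.1": "+", "HD1.2": "+", "HD1.3": "-", "HD2.2": "+"}

_TYPE_CLASSES = {
    "Type1": ("HD1.1", "HD2.1", "HD1.2", "HD1.3", "HD2.2"),
    "Type2": ("HD1.1", "HD1.2", "HD1.3", "HD2.2"),
    "Type3": ("HD1.1", "HD2.1", "HD1.2", "HD2.2"),
    "Type4": ("HD1.1", "HD1.2", "HD2.2"),
}

_RECEPTOR_INTRONS = {"STE3.1": 5, "STE3.2": 5, "STE3.3": 4, "STE3.s1": 4, "STE3.s2": 5}

DEFAULT_DECOYS = ("no_caax", "no_anchor", "too_long", "outside_window")


def _rng(*parts) -> np.random.Generator:
    """Deterministic generator keyed on arbitrary hashable parts."""
    key = zlib.crc32("\x1f".join(str(p) for p in parts).encode()) & 0x7FFFFFFF
    return np.random.default_rng(key)


# ---------------------------------------------------------------------------
# Panel proteins and coding sequences


def _random_protein(rng, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=length - 1))


def _receptor_protein(rng) -> str:
    """A 7-TM protein: seven hydrophobic 21-mers separated by hydrophilic loops."""
    parts = ["M" + "".join(rng.choice(list(_HYDROPHILIC), size=24))]
    for i in range(7):
        parts.append("".join(rng.choice(list(_HYDROPHOBIC), size=21)))
        loop = 40 if i == 6 else int(rng.integers(13, 19))
        parts.append("".join(rng.choice(list(_HYDROPHILIC), size=loop)))
    return "".join(parts)


_PANEL_LENGTHS = {
    "Mip": 380,
    "Bfg": 300,
    "HD1.1": 450,
    "HD1.2": 430,
    "HD1.3": 410,
    "HD2.1": 470,
    "HD2.2": 440,
}


_PANEL_CACHE: list = []


def build_default_panel() -> ReferencePanel:
    """The packaged synthetic reference panel (deterministic)."""
    if _PANEL_CACHE:
        return _PANEL_CACHE[0]
    entries = []
    for label, length in _PANEL_LENGTHS.items():
        rng = _rng(PANEL_SEED, "panel", label)
        entries.append(PanelEntry(label, _random_protein(rng, length), "synthetic panel"))
    for label in _RECEPTOR_INTRONS:
        rng = _rng(PANEL_SEED, "panel", label)
        entries.append(PanelEntry(label, _receptor_protein(rng), "synthetic panel"))
    panel = ReferencePanel(entries)
    _PANEL_CACHE.append(panel)
    return panel


_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


_STOPS = ("TAA", "TAG", "TGA")


def back_translate(protein: str, rng, add_stop: bool = True) -> str:
    """Random-codon realisation of a protein (ATG start, optional stop codon)."""
    table = _codon_table()
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            codons.append("ATG")
        else:
            opts = table[aa]
            codons.append(opts[rng.integers(0, len(opts))])
    if add_stop:
        codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _mutate_cds(cds: str, divergence: float, rng) -> str:
    """Substitute ~divergence of positions, never creating an in-frame stop."""
    seq = list(cds)
    n_mut = int(round(divergence * len(seq)))
    positions = rng.choice(np.arange(3, len(seq) - 3), size=min(n_mut, len(seq) - 6), replace=False)
    for pos in positions:
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for new in choices:
            seq[pos] = new
            c0 = (pos // 3) * 3
            if "".join(seq[c0 : c0 + 3]) not in _STOPS:
                break
            seq[pos] = old
    return "".join(seq)


@lru_cache(maxsize=None)
def allele_cds(class_label: str, allele_id: str) -> str:
    """Deterministic allelic CDS for a panel class.

    The base CDS is a fixed back-translation of the class's panel protein;
    each allele id applies its own 1-4% of seeded substitutions, so different
    alleles share the class (classification is unambiguous) but carry
    distinct sequences (fingerprints differ). Includes the stop codon.
    """
    panel = build_default_panel()
    prot = next(e.protein for e in panel if e.class_label == class_label)
    base = back_translate(prot, _rng(PANEL_SEED, "base-cds", class_label))
    arng = _rng(PANEL_SEED, "allele", class_label, allele_id)
    divergence = float(arng.uniform(0.01, 0.04))
    return _mutate_cds(base, divergence, arng)


# ---------------------------------------------------------------------------
# Contig assembly


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


class _ContigBuilder:
    def __init__(self, contig_id: str, rng):
        self.contig_id = contig_id
        self.rng = rng
        self.parts: list[str] = []
        self.pos = 0
        self.models: list[GeneModel] = []

    def append(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def spacer(self, lo: int, hi: int) -> None:
        self.append(_random_dna(self.rng, int(self.rng.integers(lo, hi + 1))))

    def add_gene(self, gene_id: str, cds: str, strand: str, n_introns: int) -> GeneModel:
        """Place a gene: CDS split into exons separated by GT..AG introns."""
        cuts = sorted(
            self.rng.choice(np.arange(1, len(cds)), size=n_introns, replace=False)
        ) if n_introns else []
        chunks = []
        prev = 0
        for c in list(cuts) + [len(cds)]:
            chunks.append(cds[prev:c])
            prev = c
        pieces: list[tuple[str, bool]] = []
        for i, chunk in enumerate(chunks):
            pieces.append((chunk, True))
            if i < len(chunks) - 1:
                ilen = int(self.rng.integers(60, 201))
                pieces.append(("GT" + _random_dna(self.rng, ilen - 4) + "AG", False))
        plus = "".join(p for p, _ in pieces)
        rel: list[tuple[int, int]] = []
        off = 0
        for p, is_exon in pieces:
            if is_exon:
                rel.append((off, off + len(p)))
            off += len(p)
        if strand == "-":
            plus = reverse_complement(plus)
            L = len(plus)
            rel = sorted((L - e, L - s) for s, e in rel)
        start, end = self.append(plus)
        cds_abs = [(start + s, start + e) for s, e in rel]
        model = GeneModel(
            gene_id=gene_id,
            contig_id=self.contig_id,
            strand=strand,
            start=start,
            end=end,
            exons=list(cds_abs),
            cds=cds_abs,
            protein=translate_cds(cds if strand == "+" else cds),
        )
        self.models.append(model)
        return model

    def add_orf(self, orf_nt: str, strand: str, insulate: bool = True) -> tuple[int, int]:
        """Plant a raw ORF (no gene model), framed by all-frame stop insulators."""
        seq = orf_nt if strand == "+" else reverse_complement(orf_nt)
        if insulate:
            self.append(_INSULATOR)
        span = self.append(seq)
        if insulate:
            self.append(_INSULATOR)
        return span

    def contig(self) -> Contig:
        return Contig(self.contig_id, "".join(self.parts))


# ---------------------------------------------------------------------------
# HD haplotypes


def generate_hd_haplotype(
    hd_type: str, allele_id: str, seed, contig_id: str = "hd", gene_prefix: str = "g"
):
    """One HD-locus contig: Mip, the Type's HD genes, Bfg, plus flanks.

    Returns (Contig, [GeneModel], truth dict). The truth carries the planted
    Type, per-gene classes and the haplotype's allele fingerprint (hash of
    the HD coding sequences).
    """
    if hd_type not in _TYPE_CLASSES:
        raise ValueError(f"unknown haplotype type {hd_type!r}")
    rng = _rng(seed, "hd", hd_type, allele_id, contig_id)
    b = _ContigBuilder(contig_id, rng)
    b.spacer(300, 800)
    genes: list[dict] = []
    plan = [("Mip", "+")]
    plan += [(c, _HD_STRANDS[c]) for c in CANONICAL_ORDER if c in _TYPE_CLASSES[hd_type]]
    plan += [("Bfg", "+")]
    hd_cds: list[str] = []
    for i, (label, strand) in enumerate(plan):
        cds = allele_cds(label, allele_id)
        n_int = int(rng.integers(1, 4))
        model = b.add_gene(f"{gene_prefix}{i + 1:02d}", cds, strand, n_int)
        genes.append(
            {"gene_id": model.gene_id, "class": label, "strand": strand,
             "start": model.start, "end": model.end}
        )
        if label.startswith("HD"):
            hd_cds.append(cds)
        if i < len(plan) - 1:
            b.spacer(200, 2000)
    b.spacer(300, 800)
    contig = b.contig()
    truth = {
        "contig": contig_id,
        "kind": "hd",
        "type": hd_type,
        "allele_id": allele_id,
        "interval": [genes[0]["start"], genes[-1]["end"]],
        "genes": genes,
        "fingerprint": allele_fingerprint(hd_cds),
    }
    return contig, b.models, truth


# ---------------------------------------------------------------------------
# P/R haplotypes


def _phb_peptide(rng, motif: str, length: int = 50, anchor_offset: int = 10) -> str:
    """Pheromone-precursor peptide: M..., Glu ``anchor_offset`` before the CAAX Cys.

    Residues between the anchor and the motif (offsets < anchor_offset) are
    kept free of E/D so the smallest in-window acidic offset is exactly
    ``anchor_offset``.
    """
    no_acid = [a for a in AA20 if a not in "ED"]
    body_len = length - 4  # residues before the CAAX block
    body = ["M"] + [str(rng.choice(no_acid)) for _ in range(body_len - 1)]
    cys_index = length - 4
    anchor_index = cys_index - anchor_offset
    body[anchor_index] = "E"
    return "".join(body) + motif


def _decoy_peptide(rng, kind: str) -> str:
    """Peptides violating exactly one precursor rule each."""
    if kind == "no_caax":
        return _phb_peptide(rng, "AVIA")  # anchor present, C missing at -4
    if kind == "no_anchor":
        no_acid = [a for a in AA20 if a not in "ED"]
        body = ["M"] + [str(rng.choice(no_acid)) for _ in range(45)]
        return "".join(body) + "CVIA"  # no E/D anywhere upstream
    if kind == "too_long":
        return _phb_peptide(rng, "CVIA", length=120)
    if kind == "outside_window":
        return _phb_peptide(rng, "CVIA")
    raise ValueError(f"unknown decoy kind {kind!r}")


_EXPECTED_DECOY_REASON = {
    "no_caax": "no CAAX",
    "no_anchor": "no acidic anchor",
    "too_long": "too long",
    "outside_window": "outside window",
}


def _build_pr_contig(b_allele_id, rng, contig_id, gene_prefix, decoys):
    b = _ContigBuilder(contig_id, rng)
    b.spacer(300, 700)
    receptors: list[dict] = []
    others: list[dict] = []
    phbs: list[dict] = []
    decoy_truth: list[dict] = []
    gi = 0

    def place_receptor(label, strand):
        nonlocal gi
        gi += 1
        cds = allele_cds(label, b_allele_id)
        model = b.add_gene(f"{gene_prefix}{gi:02d}", cds, strand, _RECEPTOR_INTRONS[label])
        receptors.append(
            {"gene_id": model.gene_id, "class": label, "strand": strand,
             "start": model.start, "end": model.end, "introns": model.intron_count,
             "cds": cds}
        )

    def place_hp(name):
        nonlocal gi
        gi += 1
        prot = _random_protein(rng, int(rng.integers(150, 251)))
        cds = back_translate(prot, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        model = b.add_gene(f"{gene_prefix}{gi:02d}", cds, strand, int(rng.integers(0, 3)))
        others.append({"gene_id": model.gene_id, "role": name, "strand": strand,
                       "start": model.start, "end": model.end})

    def place_phb(name, motif):
        pep = _phb_peptide(rng, motif)
        orf_nt = back_translate(pep, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        span = b.add_orf(orf_nt, strand)
        phbs.append({"name": name, "motif": motif, "strand": strand,
                     "start": span[0], "end": span[1], "length_aa": len(pep),
                     "glu_offset": 10})

    def place_decoy(kind):
        pep = _decoy_peptide(rng, kind)
        orf_nt = back_translate(pep, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        span = b.add_orf(orf_nt, strand)
        decoy_truth.append({"kind": kind, "strand": strand, "start": span[0],
                            "end": span[1], "expected_reason": _EXPECTED_DECOY_REASON[kind]})

    inner_decoys = [d for d in decoys if d != "outside_window"]

    place_receptor("STE3.s1", "+")
    b.spacer(300, 900)
    place_receptor("STE3.1", "-")
    b.spacer(200, 600)
    place_phb("PHB1", "CVIA")
    if "no_caax" in inner_decoys:
        b.spacer(150, 400)
        place_decoy("no_caax")
    b.spacer(300, 900)
    place_receptor("STE3.2", "+")
    b.spacer(200, 600)
    place_hp("HP1")
    if "no_anchor" in inner_decoys:
        b.spacer(150, 400)
        place_decoy("no_anchor")
    b.spacer(200, 600)
    place_phb("PHB3", "CVIA")  # PHB3 and PHB2 flank STE3.3
    b.spacer(200, 600)
    place_receptor("STE3.3", "-")
    b.spacer(200, 600)
    place_phb("PHB2", "CTIS")
    if "too_long" in inner_decoys:
        b.spacer(150, 400)
        place_decoy("too_long")
    b.spacer(200, 600)
    place_hp("HP2")
    b.spacer(300, 900)
    place_receptor("STE3.s2", "+")
    b.spacer(200, 600)
    place_hp("HP3")
    if "outside_window" in decoys:
        # past the 5 kb window of the rightmost receptor but inside scan reach
        gap_needed = 6200 - (b.pos - receptors[-1]["end"])
        if gap_needed > 0:
            b.append(_random_dna(rng, gap_needed))
        place_decoy("outside_window")
    b.spacer(300, 700)
    return b.contig(), b.models, receptors, others, phbs, decoy_truth


def generate_pr_haplotype(
    b_allele_id: str,
    seed,
    contig_id: str = "pr",
    gene_prefix: str = "p",
    decoys: tuple = DEFAULT_DECOYS,
    params: PheromoneParams = PheromoneParams(),
    max_attempts: int = 60,
):
    """One P/R-locus contig with receptors, pheromone ORFs and decoys.

    The random intergenic background can by chance contain an ORF satisfying
    all four precursor rules; candidate contigs are therefore re-drawn (with
    a deterministic attempt counter) until mining the contig recovers exactly
    the planted precursors — the emitted genome is guaranteed consistent with
    its truth table. Returns (Contig, [GeneModel], truth dict).
    """
    for attempt in range(max_attempts):
        rng = _rng(seed, "pr", b_allele_id, contig_id, attempt)
        contig, models, receptors, others, phbs, decoy_truth = _build_pr_contig(
            b_allele_id, rng, contig_id, gene_prefix, decoys
        )
        rec_models = [m for m in models if any(r["gene_id"] == m.gene_id for r in receptors)]
        calls = mine_pheromones(contig, rec_models, params)
        accepted = {(c.orf.strand, c.orf.start, c.orf.end) for c in calls if c.verdict == "accept"}
        planted = {(p["strand"], p["start"], p["end"]) for p in phbs}
        if accepted != planted:
            continue
        by_span = {(c.orf.strand, c.orf.start, c.orf.end): c for c in calls}
        ok = True
        for d in decoy_truth:
            c = by_span.get((d["strand"], d["start"], d["end"]))
            if c is None or c.verdict != "reject" or d["expected_reason"] not in c.reject_reasons:
                ok = False
                break
        if not ok:
            continue
        truth = {
            "contig": contig_id,
            "kind": "pr",
            "b_allele_id": b_allele_id,
            "interval": [min(r["start"] for r in receptors), max(r["end"] for r in receptors)],
            "receptors": [{k: v for k, v in r.items() if k != "cds"} for r in receptors],
            "pheromones": phbs,
            "hypothetical": others,
            "decoys": decoy_truth,
            "fingerprint": allele_fingerprint([r["cds"] for r in receptors]),
            "attempt": attempt,
        }
        return contig, models, truth
    raise RuntimeError(
        f"could not generate a clean P/R contig for {b_allele_id!r} in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Strains and populations


@dataclass
class StrainSpec:
    """Recipe for one synthetic strain.

    Dikaryons carry two HD haplotypes and two P/R alleles; (type, allele)
    combinations must differ between the two nuclei unless
    ``allow_incompatible`` is set (for negative tests).
    """

    strain_id: str
    karyotype: str                        # 'mono' | 'di'
    hd_types: tuple[str, ...]
    hd_allele_ids: tuple[str, ...]
    b_allele_ids: tuple[str, ...]
    decoys: tuple[str, ...] = DEFAULT_DECOYS
    with_pr: bool = True
    allow_incompatible: bool = False

    def __post_init__(self):
        n = 2 if self.karyotype == "di" else 1
        if not (len(self.hd_types) == len(self.hd_allele_ids) == n):
            raise ValueError(f"{self.strain_id}: {self.karyotype} needs {n} HD haplotype(s)")
        if self.with_pr and len(self.b_allele_ids) != n:
            raise ValueError(f"{self.strain_id}: {self.karyotype} needs {n} B allele(s)")
        if self.karyotype == "di" and not self.allow_incompatible:
            if (self.hd_types[0], self.hd_allele_ids[0]) == (self.hd_types[1], self.hd_allele_ids[1]):
                raise ValueError(
                    f"{self.strain_id}: dikaryon with two identical HD haplotypes "
                    "(set allow_incompatible to force)"
                )


def generate_strain(spec: StrainSpec, seed):
    """Build all contigs/models/truth for one strain (no file output)."""
    contigs, models = [], []
    truth = {"strain_id": spec.strain_id, "karyotype": spec.karyotype, "haplotypes": []}
    tags = ["A", "B"][: 2 if spec.karyotype == "di" else 1]
    for i, tag in enumerate(tags):
        cid = f"{spec.strain_id}_hd{tag}"
        c, m, t = generate_hd_haplotype(
            spec.hd_types[i], spec.hd_allele_ids[i], seed, cid, gene_prefix=f"{cid}_g"
        )
        contigs.append(c)
        models.extend(m)
        truth["haplotypes"].append(t)
        if spec.with_pr:
            pid = f"{spec.strain_id}_pr{tag}"
            c, m, t = generate_pr_haplotype(
                spec.b_allele_ids[i], seed, pid, gene_prefix=f"{pid}_g", decoys=spec.decoys
            )
            contigs.append(c)
            models.extend(m)
            truth["haplotypes"].append(t)
    return contigs, models, truth


def generate_population(specs: list[StrainSpec], outdir: str | os.PathLike, seed: int):
    """Write strains/<id>/genome.fasta + genes.gff3, truth.tsv and truth.json.

    Per-strain seeds are derived from ``seed`` and the strain id, so adding
    or removing strains never perturbs the others.
    """
    outdir = Path(outdir)
    (outdir / "strains").mkdir(parents=True, exist_ok=True)
    all_truth = []
    rows = []
    for spec in specs:
        sdir = outdir / "strains" / spec.strain_id
        sdir.mkdir(parents=True, exist_ok=True)
        contigs, models, truth = generate_strain(spec, _strain_seed(seed, spec.strain_id))
        write_fasta(contigs, sdir / "genome.fasta")
        write_gff(models, sdir / "genes.gff3")
        all_truth.append(truth)
        hd = [h for h in truth["haplotypes"] if h["kind"] == "hd"]
        pr = [h for h in truth["haplotypes"] if h["kind"] == "pr"]
        rows.append(
            {
                "strain_id": spec.strain_id,
                "karyotype": spec.karyotype,
                "type_a": hd[0]["type"],
                "type_b": hd[1]["type"] if len(hd) > 1 else "",
                "allele_fp1": hd[0]["fingerprint"],
                "allele_fp2": hd[1]["fingerprint"] if len(hd) > 1 else "",
                "b_fp1": pr[0]["fingerprint"] if pr else "",
                "b_fp2": pr[1]["fingerprint"] if len(pr) > 1 else "",
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(all_truth, fh, indent=1)
    return table, all_truth


def _strain_seed(seed: int, strain_id: str) -> int:
    return zlib.crc32(f"{seed}:{strain_id}".encode()) & 0x7FFFFFFF


def random_specs(n: int, seed: int, with_pr: bool = True) -> list[StrainSpec]:
    """n random strain recipes: mixed karyotypes, types and allele ids."""
    rng = np.random.default_rng(seed)
    types = list(_TYPE_CLASSES)
    specs = []
    for i in range(n):
        sid = f"syn{i + 1:03d}"
        karyotype = "di" if rng.random() < 0.6 else "mono"
        if karyotype == "mono":
            t = (str(rng.choice(types)),)
            a = (f"a{int(rng.integers(1, 4))}",)
            bb = (f"b{int(rng.integers(1, 5))}",)
        else:
            t1, t2 = rng.choice(types, size=2, replace=True)
            a1 = f"a{int(rng.integers(1, 4))}"
            a2 = f"a{int(rng.integers(1, 4))}"
            if (t1, a1) == (t2, a2):  # force compatible nuclei
                a2 = f"a{(int(a1[1:]) % 3) + 1}"
            b1 = f"b{int(rng.integers(1, 5))}"
            b2 = f"b{int(rng.integers(1, 5))}"
            if b1 == b2:
                b2 = f"b{(int(b1[1:]) % 4) + 1}"
            t, a, bb = (str(t1), str(t2)), (a1, a2), (b1, b2)
        specs.append(StrainSpec(sid, karyotype, t, a, bb, with_pr=with_pr))
    return specs


def table1_specs(limit: int | None = None, with_pr: bool = False) -> list[StrainSpec]:
    """Strain recipes replicating the packaged dikaryon roster.

    Each listed dikaryon is planted with its two listed haplotype Types;
    same-type pairs get distinct allele ids so the nuclei stay compatible.
    Strain ids are made unique positionally (the printed roster reuses one id).
    """
    roster = load_table1()
    specs = []
    for i, row in enumerate(roster.itertuples(index=False)):
        if limit is not None and i >= limit:
            break
        t1, t2 = row.type_a, row.type_b
        a1, a2 = ("a1", "a2") if t1 == t2 else ("a1", "a1")
        b1, b2 = "b1", "b2"
        specs.append(
            StrainSpec(
                f"{row.strain_id}_{i:02d}", "di", (t1, t2), (a1, a2), (b1, b2),
                with_pr=with_pr,
            )
        )
    return specs
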