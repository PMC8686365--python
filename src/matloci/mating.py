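"""Tetrapolar mating-compatibility prediction and cross simulation.

Two monokaryons mate iff they differ at BOTH unlinked mating-type loci: the
HD (MAT-A) locus and the pheromone/receptor (MAT-B) locus. Allele identity
is decided by a canonical fingerprint of the locus's coding sequences, so
two haplotypes of the same gene-content Type can still be compatible when
their allelic sequences differ (Type 1 x Type 1 dikaryons exist in the
natural population). Meiosis is modelled with free recombination between
the two loci and full linkage within each (recombination at mating-type
loci is suppressed), so a compatible cross yields exactly the four A x B
recombinant classes at expected frequency 1/4 each.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HDHaplotype",
    "MatGenotype",
    "CrossResult",
    "IncompatibleCrossError",
    "IncompleteGenotypeError",
    "allele_fingerprint",
    "collapse_alleles",
    "hd_compatible",
    "tetrapolar_compatible",
    "simulate_cross",
    "validate_dikaryon",
    "compatibility_matrix",
]


class IncompatibleCrossError(ValueError):
    """Cross refused: parents share an allele at one or both mating-type loci."""


class IncompleteGenotypeError(ValueError):
    """A genotype is missing its A or B locus."""


def allele_fingerprint(sequences) -> str:
    """Canonical hash of a locus's coding sequences (case/order normalised)."""
    seqs = sorted(s.upper() for s in sequences)
    return hashlib.sha256("|".join(seqs).encode()).hexdigest()[:16]


def collapse_alleles(allele_seqs: dict[str, list[str]], min_identity: float = 0.995) -> dict[str, str]:
    """Group near-identical alleles and map each key to one canonical fingerprint.

    Guards against sequencing noise: two alleles whose concatenated coding
    sequences align at >= ``min_identity`` (edlib edit distance over the
    longer length) are treated as the same allele. Returns
    {key -> fingerprint}, with a shared fingerprint per collapsed group.
    """
    import edlib

    keys = sorted(allele_seqs)
    concat = {k: "".join(sorted(s.upper() for s in allele_seqs[k])) for k in keys}
    canon: dict[str, str] = {}
    reps: list[str] = []  # representative keys
    for k in keys:
        match = None
        for r in reps:
            a, b = concat[k], concat[r]
            d = edlib.align(a, b, task="distance")["editDistance"]
            if 1 - d / max(len(a), len(b)) >= min_identity:
                match = r
                break
        if match is None:
            reps.append(k)
            canon[k] = allele_fingerprint(allele_seqs[k])
        else:
            canon[k] = canon[match]
    return canon


@dataclass(frozen=True)
class HDHaplotype:
    htype: str          # Type1..Type4
    fingerprint: str    # allele fingerprint of the HD coding sequences


@dataclass(frozen=True)
class MatGenotype:
    a_locus: HDHaplotype | None
    b_allele: str | None          # fingerprint of the P/R locus sequences
    label: str = ""

    def require_complete(self):
        if self.a_locus is None or self.b_allele is None:
            raise IncompleteGenotypeError(f"incomplete genotype {self.label or self!r}")


def hd_compatible(h1: HDHaplotype, h2: HDHaplotype) -> bool:
    """A-locus compatibility: true iff allele fingerprints differ.

    Different Types imply different fingerprints; equal Types may still be
    compatible when the allelic sequences differ.
    """
    return h1.fingerprint != h2.fingerprint


def tetrapolar_compatible(g1: MatGenotype, g2: MatGenotype) -> bool:
    """True iff the parents differ at both the A and the B locus."""
    g1.require_complete()
    g2.require_complete()
    return hd_compatible(g1.a_locus, g2.a_locus) and g1.b_allele != g2.b_allele


@dataclass
class CrossResult:
    parents: tuple[MatGenotype, MatGenotype]
    progeny_classes: list[MatGenotype]            # the four A x B recombinant classes
    class_labels: list[str]                       # e.g. A1B1, A1B2, A2B1, A2B2
    sibling_matrix: np.ndarray                    # 4x4 bool, symmetric, False diagonal
    compatible_pairs: list[tuple[str, str]]       # unordered compatible class pairs
    sampled_counts: dict[str, int] = field(default_factory=dict)
    sampled_progeny: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "parents": [p.label for p in self.parents],
                "classes": self.class_labels,
                "compatible_pairs": self.compatible_pairs,
                "sampled_counts": self.sampled_counts,
            },
            indent=2,
        )


def simulate_cross(
    g1: MatGenotype,
    g2: MatGenotype,
    n_progeny: int = 0,
    seed: int | None = None,
    keep_progeny: bool = False,
) -> CrossResult:
    """Simulate a compatible cross: enumerate F1 classes and their sib matings.

    Progeny are drawn uniformly from the four recombinant classes (free
    recombination between unlinked loci, none within a locus). The sibling
    matrix applies the tetrapolar rule to every class pair; for any
    compatible cross exactly two of the six unordered pairs are compatible
    (the two fully-recombinant pairings).
    """
    if not tetrapolar_compatible(g1, g2):
        raise IncompatibleCrossError(
            f"parents {g1.label or 'g1'} x {g2.label or 'g2'} share a mating-type allele"
        )
    a_alleles = [(g1.a_locus, "A1"), (g2.a_locus, "A2")]
    b_alleles = [(g1.b_allele, "B1"), (g2.b_allele, "B2")]
    classes, labels = [], []
    for a, an in a_alleles:
        for b, bn in b_alleles:
            labels.append(an + bn)
            classes.append(MatGenotype(a, b, label=an + bn))
    m = np.zeros((4, 4), dtype=bool)
    for i in range(4):
        for j in range(i + 1, 4):
            m[i, j] = m[j, i] = tetrapolar_compatible(classes[i], classes[j])
    pairs = [
        (labels[i], labels[j]) for i in range(4) for j in range(i + 1, 4) if m[i, j]
    ]
    counts: dict[str, int] = {}
    progeny: list[str] = []
    if n_progeny:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 4, size=n_progeny)
        counts = {labels[k]: int((draws == k).sum()) for k in range(4)}
        if keep_progeny:
            progeny = [labels[k] for k in draws]
    return CrossResult((g1, g2), classes, labels, m, pairs, counts, progeny)


def validate_dikaryon(haplotypes: list[HDHaplotype]) -> tuple[str, str]:
    """QC a strain's HD haplotype pair: dikaryons must carry compatible alleles.

    Returns (verdict, detail) with verdict in {'pass', 'fail',
    'not-applicable'}; monokaryons (one haplotype) are not applicable.
    """
    if len(haplotypes) == 1:
        return "not-applicable", "monokaryon: single haplotype"
    if len(haplotypes) != 2:
        return "fail", f"expected 1 or 2 haplotypes, got {len(haplotypes)}"
    h1, h2 = haplotypes
    if hd_compatible(h1, h2):
        return "pass", f"{h1.htype}/{h2.htype} with distinct alleles"
    return "fail", f"shared allele fingerprint {h1.fingerprint}"


def compatibility_matrix(genotypes: list[MatGenotype]):
    """Pairwise tetrapolar compatibility over a strain panel (pandas DataFrame)."""
    import pandas as pd

    names = [g.label or f"g{i}" for i, g in enumerate(genotypes)]
    n = len(genotypes)
    mat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j:
                mat[i, j] = tetrapolar_compatible(genotypes[i], genotypes[j])
    return pd.DataFrame(mat, index=names, columns=names)


def write_compatibility_tsv(df, path: str | os.PathLike) -> None:
    df.astype(int).to_csv(path, sep="\t")
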