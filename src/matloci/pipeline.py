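"""End-to-end strain annotation: homology -> HD typing -> pheromone mining.

Glue over the stage modules so the CLI, the analysis drivers and the tests
run the same computation. The result bundles, per strain assembly: panel
hits, located/typed HD loci with allele fingerprints, P/R loci with accepted
pheromone calls, and the inferred mating genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import hd_typing, homology, mating, pheromone
from .homology import STE3_LABELS, ReferencePanel
from .pheromone import PheromoneParams
from .seqio import Contig, GeneModel


@dataclass
class StrainReport:
    strain_id: str
    hits: dict = field(default_factory=dict)
    hd_loci: list = field(default_factory=list)
    hd_types: dict = field(default_factory=dict)          # contig -> Type (complete loci)
    hd_fingerprints: dict = field(default_factory=dict)   # contig -> allele fingerprint
    pr_loci: list = field(default_factory=list)
    pr_fingerprints: dict = field(default_factory=dict)   # contig -> B-locus fingerprint
    calls: list = field(default_factory=list)             # every PheromoneCall, all contigs
    warnings: list = field(default_factory=list)

    @property
    def karyotype(self) -> str:
        n = len(self.hd_types)
        return {1: "mono", 2: "di"}.get(n, f"{n}-haplotype")

    def genotypes(self) -> list[mating.MatGenotype]:
        """One MatGenotype per haplotype, pairing HD and P/R contigs by order."""
        hd = sorted(self.hd_types)
        pr = sorted(self.pr_fingerprints)
        out = []
        for i, contig in enumerate(hd):
            hap = mating.HDHaplotype(self.hd_types[contig], self.hd_fingerprints[contig])
            b = self.pr_fingerprints[pr[i]] if i < len(pr) else None
            out.append(mating.MatGenotype(hap, b, label=f"{self.strain_id}:{contig}"))
        return out


def annotate_strain(
    strain_id: str,
    contigs: list[Contig],
    models: list[GeneModel],
    panel: ReferencePanel,
    min_identity: float = homology.DEFAULT_MIN_IDENTITY,
    min_coverage: float = homology.DEFAULT_MIN_COVERAGE,
    max_span_nt: int = hd_typing.DEFAULT_MAX_SPAN_NT,
    params: PheromoneParams = PheromoneParams(),
) -> StrainReport:
    by_contig = {c.id: c for c in contigs}
    report = StrainReport(strain_id)
    report.hits = homology.annotate_genome(models, panel, min_identity, min_coverage)

    report.hd_loci = hd_typing.locate_hd_loci(models, report.hits, max_span_nt)
    model_by_id = {m.gene_id: m for m in models}
    for locus in report.hd_loci:
        report.warnings.extend(locus.warnings)
        if not locus.complete:
            continue
        try:
            report.hd_types[locus.contig_id] = hd_typing.type_haplotype(locus)
        except hd_typing.NonCanonicalHaplotypeError as exc:
            report.warnings.append(f"{locus.contig_id}: {exc}")
            continue
        hd_cds = [
            model_by_id[gid].spliced_cds(by_contig[locus.contig_id])
            for gid in locus.gene_ids
        ]
        report.hd_fingerprints[locus.contig_id] = mating.allele_fingerprint(hd_cds)

    receptors_by_contig: dict[str, list[tuple[GeneModel, str]]] = {}
    for gid, hit in report.hits.items():
        if hit.class_label in STE3_LABELS:
            m = model_by_id[gid]
            receptors_by_contig.setdefault(m.contig_id, []).append((m, hit.class_label))
    for contig_id, recs in sorted(receptors_by_contig.items()):
        contig = by_contig[contig_id]
        calls = pheromone.mine_pheromones(contig, [m for m, _ in recs], params)
        report.calls.extend(calls)
        accepted = [c for c in calls if c.verdict == "accept"]
        loci = pheromone.assemble_pr_locus(contig, recs, accepted)
        report.pr_loci.extend(loci)
        for locus in loci:
            report.warnings.extend(locus.warnings)
        report.pr_fingerprints[contig_id] = mating.allele_fingerprint(
            [m.spliced_cds(contig) for m, _ in recs]
        )
    return report
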