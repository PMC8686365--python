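# Methods

## The biological model

Tetrapolar agaricomycetes control mating with two unlinked loci. The HD
locus (MAT-A) encodes homeodomain transcription factors whose cross-
haplotype HD1–HD2 heterodimers license post-mating development; the P/R
locus (MAT-B) encodes STE3-family G-protein-coupled pheromone receptors and
short lipopeptide pheromone precursors that mediate partner recognition.
Recombination is suppressed within each locus, so each behaves as a single
Mendelian allele; the two loci recombine freely with respect to each other.
matloci implements this model literally: a haplotype is typed by the gene
content of its HD locus, allele identity is sequence identity of the locus,
compatibility requires inequality at both loci, and meiosis shuffles the
two parental alleles of each locus independently.

## HD locus extraction and typing

Proteins are classified against a small reference panel by full
Smith–Waterman local alignment (BLOSUM62, gap open 11, extend 1), the
package's stand-in for a BLASTP search: the panel holds a dozen sequences,
so exhaustive alignment is cheap and needs no E-value model. A hit requires
≥ 40 % identity over the aligned columns and ≥ 50 % coverage of the
reference. Both thresholds are deliberately permissive — alleles of one
class differ by a few percent, while different classes are unrelated — and
are configurable. Ties are broken by score, then identity, then
lexicographic class label, making classification independent of panel and
query order.

The HD locus is anchored on a Mip/Bfg pair on one contig within a maximum
span (default 100 kb; the native locus is ~16 kb, but the flank-to-flank
separation reaches tens to hundreds of kb in related species, so the
ceiling is generous and configurable). HD-classified genes between the
flags are ordered from the Mip side; a contig with only one flag yields an
explicit incomplete-locus record rather than an error. Typing is a pure
function of the class set: presence/absence of HD2.1 and HD1.3 over the
conserved core {HD1.1, HD1.2, HD2.2} gives Types 1–4; a locus missing a
core gene raises a non-canonical-haplotype error. Gene orientation is
recorded and checked (HD1/HD2 neighbours are expected to be divergently
transcribed) but deliberately not used for typing, which follows gene
content only. Dikaryon phasing is per contig: each assembled contig
carries one haplotype; read-level phasing is out of scope.

## Pheromone-precursor mining

Around every receptor gene the six-frame ORF scanner enumerates ATG→stop
ORFs (standard genetic code; alternative starts unsupported; nested ORFs
sharing a stop are reported from the most 5' ATG unless `report_nested`).
ORFs overlapping the window edge are discarded, not clipped. The window is
±5,000 nt from the receptor gene's span boundaries. The scanner actually
searches a slightly wider region (window + 2,500 nt slack) with relaxed
length bounds so that near-misses — a perfect precursor 6 kb away, a
120-aa ORF — are reported as rejections with a reason ("outside window",
"too long") instead of silently dropped; the verdict itself applies the
strict parameters.

A call is accepted iff all four rules hold:

* **CAAX** — Cys at position −4; both A positions in the aliphatic set.
  Default mode is *relaxed* ({A,V,L,I,M,T,S,C,G,F}): the natural precursor
  repertoire includes a CTIS motif, which a textbook aliphatic test
  ({A,V,L,I}, the *strict* mode) would reject. Strict acceptances are a
  subset of relaxed ones. An X (from an N-containing codon) at a
  constrained position leaves the motif present but flagged ambiguous.
* **Acidic anchor** — smallest offset in [8, 16] residues upstream of the
  CAAX Cys holding a Glu (Asp optionally accepted with `acidic_mode=ED`).
  The window covers the canonical "~10 residues upstream" position with
  room for the 10–15 range reported across genera.
* **Length** — 20–100 aa, reconciling the ">20 aa" and "40–100 aa"
  descriptions in the precursor literature; both bounds configurable.
* **Proximity** — gap between ORF and anchor receptor spans ≤ window.

Calls seen from several receptor windows are deduplicated keeping the
nearest receptor as anchor. An optional hook attaches PF08015-family
profile scores (via a user callable or pyhmmer) — scores are advisory and
never change verdicts, keeping the core fully testable offline.

Receptor QC is two-fold: a Kyte–Doolittle sliding-window hydropathy scan
(window 19, cutoff 1.6, runs merged when < 5 window-starts apart — these
are this package's choices; no specific TM predictor is being imitated)
should find 7 ± 1 segments; and gene models should carry 5 introns for
STE3.1/STE3.2/STE3.s2 and 4 for STE3.3/STE3.s1. Deviations are warnings,
not errors, because known natural haplotypes carry five-intron STE3.3
genes.

## Compatibility and crosses

An allele fingerprint is a SHA-256 prefix of the locus's coding sequences,
case-normalised and sorted, so it is invariant to gene order and strand
bookkeeping. HD compatibility is fingerprint inequality — two Type 1
haplotypes with different allelic series are compatible, matching the
existence of Type1 & Type1 dikaryons. For assemblies with sequencing
noise, `collapse_alleles` merges alleles above a near-identity threshold
(default 99.5 %, edlib edit distance) before fingerprinting; exact equality
is the default because the synthetic data is noise-free. B-locus
compatibility uses whole-locus fingerprints; pheromone–receptor molecular
recognition is not modelled (no recognition matrix exists to calibrate
one). `simulate_cross` enumerates the four A×B progeny classes, samples
them uniformly with a seeded generator, and applies the tetrapolar rule to
all sibling pairs; for any compatible cross exactly 2 of the 6 unordered
class pairs are compatible.

## Synthetic data: what it emulates, and what it does not

The generator emits the study conditions the pipeline is meant to face:
four HD haplotype architectures with divergently transcribed HD1/HD2
neighbour pairs and 200–2,000 nt spacers on a ≤ ~20 kb locus; a ~22 kb P/R
contig with the five receptor genes at their expected intron counts, three
precursors (~50 aa, CVIA/CVIA/CTIS, Glu at offset 10, PHB3 and PHB2
flanking STE3.3), three hypothetical-protein genes, and four decoy ORFs
each violating exactly one rule (no CAAX, no anchor, 120 aa, planted
~6.2 kb from the nearest receptor). Coding sequences are random-codon
realisations of a deterministic synthetic protein panel, independent of
any reference database. Allelic series apply 1–4 % seeded nucleotide
substitutions (never creating in-frame stops) to a per-class base CDS, so
classification is unambiguous while fingerprints differ. Background
sequence is uniform-GC random DNA without repeats or assembly gaps.

Random background occasionally contains a chance ORF passing all four
rules (~22 kb of double-stranded sequence yields hundreds of candidate
ORFs). Rather than emit genomes inconsistent with their truth tables, the
generator re-draws the contig with a deterministic attempt counter until
mining recovers exactly the planted set (mean ~4, bounded at 60 attempts);
planted ORFs are framed by 12-nt all-frame stop insulators so their
reported spans are stable. Everything is bit-reproducible for a fixed
seed, and per-strain seeds are derived from the population seed and strain
id so populations are stable under roster edits.

Consequences for interpretation: passing the recovery tests shows the
pipeline's logic is exact under clean assemblies with moderate allelic
divergence. It does not establish robustness to fragmented loci,
repeat-rich intergenic DNA, annotation errors, or receptor paralogs beyond
the five modelled classes — real-genome use should supply a real reference
panel and treat warnings (incomplete loci, unexpected intron counts,
non-7-TM receptors) as signals for manual review.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
  1-based inclusive.
* Codons containing N translate to X; X at constrained motif positions
  flags the call as ambiguous instead of auto-rejecting it.
* Smith–Waterman identity counts identities over all aligned columns
  (gaps included), BLAST-style; coverage is measured on the reference.
* The packaged dikaryon roster is stored verbatim as printed, including
  one strain id that appears in two groups; counting is row-based.
* Analysis scripts default to a 12-strain simulated population and an
  8-strain roster slice for the end-to-end replica; the acceptance script
  uses a 20-strain population. These sizes exercise every code path,
  including same-type dikaryons, while each stage completes in seconds.
* χ² goodness-of-fit for cross segregation uses n = 10,000 progeny at
  α = 0.01.

## Known limitations

No read-level phasing, no assembly or gene prediction, no phylogenetics
(class membership is inherited from best-hit labels, not trees), no
NLS/coiled-coil annotation, no expression data, and no model of
pheromone–receptor specificity within the B locus.
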