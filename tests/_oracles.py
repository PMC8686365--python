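"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: enumerate every ATG/stop pair in every frame by direct
string scanning, with no shared code with matloci.seqio.
"""

STOPS = {"TAA", "TAG", "TGA"}

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def _translate(seq):
    return "".join(_CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3))


def _orfs_one_strand(seq):
    """All (start, end, peptide) ATG..stop pairs, end past the stop codon."""
    found = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                found.append((i, j + 3, _translate(seq[i:j])))
                break
            j += 3
    return found


def brute_force_orfs(sequence, window, min_aa, max_aa, nested=True):
    """All six-frame ORFs fully inside window, forward-strand coordinates.

    Returns a set of (strand, start, end, peptide). With nested=False, only
    the most 5' ATG per (strand, stop) group is kept.
    """
    lo = max(0, window[0])
    hi = min(len(sequence), window[1])
    sub = sequence[lo:hi]
    m = len(sub)
    hits = []
    for s, e, pep in _orfs_one_strand(sub):
        hits.append(("+", lo + s, lo + e, pep, lo + e))
    for s, e, pep in _orfs_one_strand(_revcomp(sub)):
        hits.append(("-", lo + m - e, lo + m - s, pep, lo + m - e))
    if not nested:
        best = {}
        for strand, s, e, pep, stop in hits:
            key = (strand, stop)
            keep = best.get(key)
            # most 5' ATG = longest peptide within the stop group
            if keep is None or len(pep) > len(keep[3]):
                best[key] = (strand, s, e, pep, stop)
        hits = list(best.values())
    return {
        (strand, s, e, pep)
        for strand, s, e, pep, _ in hits
        if min_aa <= len(pep) <= max_aa
    }
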