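"""Genetic-code tables and Nei–Gojobori (1986) per-codon counting.

Uses the universal genetic code (NCBI table 1, via Biopython).  Two
primitives live here: synonymous/nonsynonymous *site* counts for a single
codon, and pathway-averaged synonymous/nonsynonymous *substitution* counts
for a codon pair.  Mutants that create stop codons count as nonsynonymous
sites; evolutionary paths passing through a stop codon are excluded from
the pathway average (unless every path is blocked, in which case all
paths are used).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

BASES = "ACGT"
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
#: codon -> amino acid one-letter code, '*' for stop
AMINO_ACID = {c: _table.forward_table.get(c, "*") for c in CODONS}
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)


@dataclass(frozen=True)
class SiteCounts:
    """Synonymous (S) and nonsynonymous (N) site counts; S + N = 3 per codon."""

    S: float
    N: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.S + other.S, self.N + other.N)


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> SiteCounts:
    """NG86 site counts for one stop-free codon.

    Each of the 9 single-nucleotide mutants contributes 1/3 of a
    synonymous site if it encodes the same amino acid, otherwise (or if
    it is a stop codon) 1/3 of a nonsynonymous site.
    """
    if not is_valid_codon(codon):
        raise ValueError(f"invalid codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon: {codon}")
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and AMINO_ACID[mutant] == aa:
                s += 1.0 / 3.0
    return SiteCounts(s, 3.0 - s)


@lru_cache(maxsize=None)
def ng86_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two stop-free codons.

    All orderings of the differing positions are enumerated; each step is
    classified synonymous or nonsynonymous by the amino acids it joins.
    Paths whose intermediate codons are stops are dropped; if every path
    is blocked, all paths are retained.  Sd + Nd equals the number of
    differing positions.
    """
    for c in (codon_a, codon_b):
        if not is_valid_codon(c):
            raise ValueError(f"invalid codon: {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon: {c}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    paths = []
    for order in permutations(diff):
        current = codon_a
        blocked = False
        syn = nonsyn = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
            if AMINO_ACID[current] == AMINO_ACID[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((blocked, syn, nonsyn))
    usable = [(s, n) for blocked, s, n in paths if not blocked]
    if not usable:
        usable = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return (sd, nd)
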