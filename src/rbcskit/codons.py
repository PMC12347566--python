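"""Standard genetic code tables shared by the simulator and the dN/dS estimator."""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from Bio.Data import CodonTable

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_standard.stop_codons)
CODON_TO_AA = dict(_standard.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))
NUCLEOTIDES = "ACGT"

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon]


@lru_cache(maxsize=None)
def synonymous_site_fractions(codon: str) -> tuple[float, float, float]:
    """Fraction of synonymous changes at each position of a sense codon.

    Changes producing a stop codon count as nonsynonymous, so each position
    contributes exactly one site split between the two classes and the
    synonymous + nonsynonymous site totals add to 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if not is_stop(mutant) and CODON_TO_AA[mutant] == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Multi-hit codon pairs are averaged over all single-step mutational
    pathways that avoid stop codons; if every ordering crosses a stop, the
    orderings crossing the fewest stops are averaged instead.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)

    scored: list[tuple[int, float, float]] = []  # (n_stops, sd, nd)
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        stops = 0
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if is_stop(nxt):
                stops += 1
                nd += 1.0  # a step through/into a stop is nonsynonymous
            elif CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        scored.append((stops, sd, nd))

    best = min(s for s, _, _ in scored)
    kept = [(sd, nd) for s, sd, nd in scored if s == best]
    sd = sum(x for x, _ in kept) / len(kept)
    nd = sum(y for _, y in kept) / len(kept)
    return (sd, nd)


def enumerate_iupac(consensus: str, table: dict[str, str]) -> list[str]:
    """All concrete sequences matching an IUPAC consensus."""
    choices = [table[c] for c in consensus]
    return ["".join(p) for p in product(*choices)]
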