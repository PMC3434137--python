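"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch — hand-typed genetic
code, integer-arithmetic hypergeometric enumeration — so it shares no code
path with the package under test.
"""

from fractions import Fraction
from itertools import product
from math import comb

# standard genetic code, hand-typed in TCAG order (independent of biopython)
_AA_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {
    "".join(codon): aa
    for codon, aa in zip(product("TCAG", repeat=3), _AA_TCAG)
}


def brute_force_snvs(codon: str):
    """All 9 single-nucleotide substitutions of one codon, by nested loops.

    Yields (pos_1based, alt_nt, alt_aa, consequence) in (position,
    alphabetical alternate) order.
    """
    ref_aa = ORACLE_CODE[codon]
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            alt_codon = codon[:pos] + alt + codon[pos + 1 :]
            alt_aa = ORACLE_CODE[alt_codon]
            if alt_aa == "*":
                consequence = "nonsense"
            elif alt_aa == ref_aa:
                consequence = "synonymous"
            else:
                consequence = "missense"
            yield pos + 1, alt, alt_aa, consequence


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact probability by exhaustive table enumeration.

    Sums hypergeometric probabilities of every 2x2 table with the observed
    margins whose probability does not exceed the observed table's.  All
    comparisons are exact integer comparisons of the shared-denominator
    weights C(r1, k) * C(r2, c1 - k).
    """
    r1, r2, c1 = a + b, c + d, a + c
    w_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= w_obs:
            total += w
    return float(Fraction(total, comb(r1 + r2, c1)))
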