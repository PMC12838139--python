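"""Independent brute-force oracles used by the test suite.

Each oracle is written directly from the definition it checks and shares no
code with the implementation under test.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

GAP_OPEN = 8.0
GAP_EXTEND = 2.0


def exhaustive_codon_alignment_score(a: list[str], b: list[str]) -> float:
    """Optimal global codon-alignment score by exhaustive recursion.

    Ops: pair a codon from each list (+1/-1 per nucleotide identity) or put
    one codon against a gap (a run of L gap codons costs 8 + 2*(L-1)).
    Feasible for inputs up to ~6 codons per list.
    """

    def go(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = sum(1.0 if x == y else -1.0 for x, y in zip(a[i], b[j]))
            best = max(best, s + go(i + 1, j + 1, "m"))
        if i < len(a):
            cost = GAP_EXTEND if last == "ga" else GAP_OPEN
            best = max(best, -cost + go(i + 1, j, "ga"))
        if j < len(b):
            cost = GAP_EXTEND if last == "gb" else GAP_OPEN
            best = max(best, -cost + go(i, j + 1, "gb"))
        return best

    return go(0, 0, "m")


def naive_binding_sites(primer: str, template: str, max_mismatch: int,
                        block_size: int) -> set[tuple[str, int]]:
    """(strand, 3'-position) pairs from a position-by-position scan.

    On the + strand the primer is read along the template left to right with
    its 3' end rightmost; on the - strand each primer base is compared to the
    complement of the template base, with the primer 3' end leftmost.
    """
    m, n = len(primer), len(template)
    sites: set[tuple[str, int]] = set()
    for start in range(n - m + 1):
        mm_plus = []
        mm_minus = []
        for k in range(m):
            t_plus = template[start + k]
            mm_plus.append(t_plus not in "ACGT" or primer[k] != t_plus)
            # primer laid antiparallel: primer base k vs template base
            # start + (m - 1 - k), complemented
            t_minus = template[start + (m - 1 - k)]
            mm_minus.append(t_minus not in "ACGT" or primer[k] != _COMP.get(t_minus, "?"))
        if sum(mm_plus) <= max_mismatch and not any(mm_plus[m - block_size:]):
            sites.add(("+", start + m))
        if sum(mm_minus) <= max_mismatch and not any(mm_minus[m - block_size:]):
            sites.add(("-", start + 1))
    return sites


def brute_force_duplex_run(seq_a: str, seq_b: str) -> int:
    """Longest perfect antiparallel Watson-Crick run between two oligos.

    Slides seq_b (3'->5', i.e. reversed) along seq_a and counts the longest
    contiguous stretch of complementary opposed bases.
    """
    b_rev = seq_b[::-1]
    best = 0
    for shift in range(-(len(b_rev) - 1), len(seq_a)):
        run = 0
        for i, base in enumerate(seq_a):
            j = i - shift
            if 0 <= j < len(b_rev) and _COMP.get(base) == b_rev[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


# Hand-summed nearest-neighbour oracle: unified dinucleotide parameters
# (dH kcal/mol, dS cal/(mol K)), re-typed from the published table with the
# reverse-complement expansion written out in full.
_NN_ORACLE = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def hand_summed_tm(seq: str, salt_mM: float = 50.0,
                   primer_conc_nM: float = 500.0) -> float:
    """Spreadsheet-style Tm: explicit term-by-term summation."""
    dh = 0.0
    ds = 0.0
    terms = [_NN_ORACLE[seq[i:i + 2]] for i in range(len(seq) - 1)]
    for h, s in terms:
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    rc = "".join(_COMP[b] for b in reversed(seq))
    if rc == seq:
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    c_quarter = primer_conc_nM * 1e-9 / 4.0
    return 1000.0 * dh / (ds + 1.987 * math.log(c_quarter)) - 273.15
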