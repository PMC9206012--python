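"""Independent brute-force oracles used by the tests.

The NG86 oracle enumerates every minimal substitution pathway between two
codons explicitly and classifies each step by translating with Biopython's
Seq.translate — a different code path from the implementation under test.
"""

from itertools import permutations

from Bio.Seq import Seq


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_diffs(a: str, b: str):
    """Pathway-averaged (syn, nonsyn) difference counts for one codon pair,
    averaging over all orderings of the differing positions."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    paths = list(permutations(positions))
    syn = nonsyn = 0
    for path in paths:
        cur = a
        for i in path:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if translate(nxt) == translate(cur) and translate(cur) != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
    return syn / len(paths), nonsyn / len(paths)


def oracle_codon_sites(codon: str):
    """(syn, nonsyn) site fractions of one codon: each position contributes
    s/3 synonymous sites over its three possible changes; stop-involving
    changes count as nonsynonymous."""
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if (translate(mutant) == translate(codon)
                    and translate(codon) != "*"):
                syn += 1
    syn /= 3.0
    return syn, 3.0 - syn


def oracle_pair_counts(seq_a: str, seq_b: str):
    """Whole-sequence (syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs)."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        s1, n1 = oracle_codon_sites(ca)
        s2, n2 = oracle_codon_sites(cb)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = oracle_codon_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd
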