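"""C2H2 zinc-finger family identification.

The family-defining domain is the classical C2H2 finger, written as
X2-C-X(2,4)-C-X12-H-X(2,8)-H: two residues, a cysteine, a short spacer, a
second cysteine, a fixed 12-residue knuckle/helix core, a histidine, a
variable spacer, and a second histidine. The two Cys and two His coordinate
a Zn(2+) ion and fold the region into a compact beta-beta-alpha finger.

This module scans protein sequences for that pattern, classifies family
membership by finger count, locates ORFs on transcripts in all six frames,
and computes ProtParam-style physicochemical properties.
"""

from __future__ import annotations

from typing import List, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import ProtParamData
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from .types import (
    AlphabetError,
    OrfRecord,
    ParameterError,
    ProteinProperties,
    SequenceRecord,
    ZincFingerHit,
)

GAP1_RANGE = range(2, 5)  # residues between the two cysteines
GAP2_RANGE = range(2, 9)  # residues between the two histidines
CORE_LEN = 12  # fixed X12 core between second Cys and first His


def _require_alphabet(record: SequenceRecord, alphabet: str) -> None:
    if record.alphabet != alphabet:
        raise AlphabetError(
            f"{record.id!r}: expected {alphabet} sequence, got {record.alphabet}"
        )


def scan_c2h2(protein: SequenceRecord) -> List[ZincFingerHit]:
    """Find every C2H2 finger by a greedy left-to-right scan.

    At each anchor position the shortest valid Cys spacer (gap1) is tried
    first, then the shortest valid His spacer (gap2); after a hit the scan
    resumes at the residue following the hit's second histidine, so reported
    hits never overlap.
    """
    _require_alphabet(protein, "protein")
    seq = protein.sequence
    hits: List[ZincFingerHit] = []
    pos = 0  # 0-based candidate start of the leading X2
    n = len(seq)
    while pos < n:
        match = _match_at(seq, pos)
        if match is None:
            pos += 1
            continue
        gap1, gap2, end = match  # end is 0-based exclusive
        hits.append(
            ZincFingerHit(
                sequence_id=protein.id,
                start=pos + 1,
                end=end,
                gap1_len=gap1,
                gap2_len=gap2,
                matched_subsequence=seq[pos:end],
            )
        )
        pos = end
    return hits


def _match_at(seq: str, pos: int) -> Tuple[int, int, int] | None:
    """Try to match the finger pattern with its X2 starting at ``pos``.

    Returns (gap1_len, gap2_len, end) with ``end`` 0-based exclusive, or
    None. Shortest gap1 wins, then shortest gap2.
    """
    if pos + 2 >= len(seq) or seq[pos + 2] != "C":
        return None
    c1 = pos + 2
    for gap1 in GAP1_RANGE:
        c2 = c1 + 1 + gap1
        if c2 >= len(seq) or seq[c2] != "C":
            continue
        h1 = c2 + 1 + CORE_LEN
        if h1 >= len(seq) or seq[h1] != "H":
            continue
        for gap2 in GAP2_RANGE:
            h2 = h1 + 1 + gap2
            if h2 >= len(seq):
                break
            if seq[h2] == "H":
                return gap1, gap2, h2 + 1
        # gap1 fixed the core/H1 position; no valid H2 means try longer gap1
    return None


def validate_hit(protein: SequenceRecord, hit: ZincFingerHit) -> bool:
    """Residue-by-residue re-validation of a reported hit (independent of
    the scanner's control flow)."""
    sub = protein.sequence[hit.start - 1 : hit.end]
    if sub != hit.matched_subsequence:
        return False
    expect_c1 = 2
    expect_c2 = 2 + 1 + hit.gap1_len
    expect_h1 = expect_c2 + 1 + CORE_LEN
    expect_h2 = expect_h1 + 1 + hit.gap2_len
    return (
        len(sub) == expect_h2 + 1
        and sub[expect_c1] == "C"
        and sub[expect_c2] == "C"
        and sub[expect_h1] == "H"
        and sub[expect_h2] == "H"
    )


def classify_family_member(
    protein: SequenceRecord, min_fingers: int = 1
) -> Tuple[bool, List[ZincFingerHit]]:
    """Classify a protein as a C2H2-ZFP family member.

    Membership requires at least ``min_fingers`` pattern hits. Family
    members typically carry one to six fingers; callers may inspect the
    returned hit list for counts outside that range.
    """
    hits = scan_c2h2(protein)
    return len(hits) >= min_fingers, hits


# --- ORF finding -----------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = set(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TO_AA = dict(standard_dna_table.forward_table)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _CODON_TO_AA.get(codon, "X")  # any N -> X


def find_orfs(
    nucleotide: SequenceRecord, min_protein_len: int = 25
) -> List[OrfRecord]:
    """Locate ATG-to-stop open reading frames in all six frames.

    Within each frame, each stop-to-stop segment contributes at most one ORF
    (from its first ATG); an ORF reaching the sequence end without a stop is
    reported with ``partial=True``. Coordinates are 1-based inclusive on the
    forward strand. Codons containing N are never treated as starts or stops
    and translate to X. Results are sorted by protein length, longest first.
    """
    _require_alphabet(nucleotide, "nucleotide")
    seq = nucleotide.sequence
    n = len(seq)
    rc = seq.translate(_COMPLEMENT)[::-1]
    orfs: List[OrfRecord] = []
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            frame = strand * (offset + 1)
            orfs.extend(
                _frame_orfs(nucleotide.id, s, offset, frame, strand, n)
            )
    orfs = [o for o in orfs if len(o.protein) >= min_protein_len]
    orfs.sort(key=lambda o: (-len(o.protein), o.frame, o.start))
    return orfs


def _frame_orfs(seq_id, s, offset, frame, strand, forward_len):
    out = []
    codons = [(i, s[i : i + 3]) for i in range(offset, len(s) - 2, 3)]
    start_idx = None  # index into codons of the segment's first ATG
    for k, (i, codon) in enumerate(codons):
        if start_idx is None and codon == "ATG":
            start_idx = k
        if codon in _STOPS:
            if start_idx is not None:
                out.append(
                    _make_orf(seq_id, codons, start_idx, k, frame, strand,
                              forward_len, partial=False)
                )
            start_idx = None
    if start_idx is not None:  # ran off the end without a stop
        out.append(
            _make_orf(seq_id, codons, start_idx, len(codons) - 1, frame,
                      strand, forward_len, partial=True)
        )
    return out


def _make_orf(seq_id, codons, start_idx, stop_idx, frame, strand,
              forward_len, partial):
    first = codons[start_idx][0]
    if partial:
        coding = codons[start_idx:]
        last = codons[-1][0] + 2
    else:
        coding = codons[start_idx:stop_idx]  # protein excludes the stop
        last = codons[stop_idx][0] + 2  # span includes the stop codon
    protein = "".join(_translate_codon(c) for _, c in coding)
    if strand == 1:
        start, end = first + 1, last + 1
    else:
        # map [first, last] on the reverse complement back to forward coords
        start = forward_len - last
        end = forward_len - first
    return OrfRecord(
        sequence_id=seq_id, frame=frame, start=start, end=end,
        protein=protein, partial=partial,
    )


# --- physicochemical properties -------------------------------------------

# average isotopic residue masses (Da); MW = sum - (L-1) * water
_WATER = 18.015
_RESIDUE_MASS = {
    "A": 89.0932, "C": 121.1582, "D": 133.1027, "E": 147.1293,
    "F": 165.1891, "G": 75.0666, "H": 155.1546, "I": 131.1729,
    "K": 146.1876, "L": 131.1729, "M": 149.2113, "N": 132.1179,
    "P": 115.1305, "Q": 146.1445, "R": 174.2010, "S": 105.0926,
    "T": 119.1192, "V": 117.1463, "W": 204.2252, "Y": 181.1885,
}


def protein_properties(protein: SequenceRecord) -> ProteinProperties:
    """Compute the standard ProtParam panel for one protein.

    Molecular weight uses average residue masses minus peptide-bond water;
    GRAVY is the mean Kyte-Doolittle hydropathy; the instability index is
    the Guruprasad dipeptide-weight statistic (10/L * sum of DIWV over
    adjacent pairs, > 40 predicts instability in vitro); the aliphatic index
    is Ikai's 100*(xAla + 2.9*xVal + 3.9*(xIle + xLeu)); and the isoelectric
    point is found by bisecting the Bjellqvist net-charge model to
    |charge| < 1e-4. X residues are excluded from every metric (documented
    exclusion; mole fractions renormalise over the remaining residues).
    """
    _require_alphabet(protein, "protein")
    seq = protein.sequence.replace("X", "")
    if not seq:
        raise ParameterError(f"{protein.id!r}: empty sequence")
    length = len(seq)

    mw = sum(_RESIDUE_MASS[a] for a in seq) - (length - 1) * _WATER
    gravy = sum(ProtParamData.kd[a] for a in seq) / length
    if length > 1:
        instability = (10.0 / length) * sum(
            ProtParamData.DIWV[a][b] for a, b in zip(seq, seq[1:])
        )
    else:
        instability = 0.0
    frac = {a: seq.count(a) / length for a in "AVIL"}
    aliphatic = 100.0 * (
        frac["A"] + 2.9 * frac["V"] + 3.9 * (frac["I"] + frac["L"])
    )
    pi = _isoelectric_point(seq)
    return ProteinProperties(
        molecular_weight=mw,
        isoelectric_point=pi,
        gravy=gravy,
        instability_index=instability,
        aliphatic_index=aliphatic,
        is_hydrophilic=gravy < 0,
        is_unstable=instability > 40.0,
    )


def _isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """Bisection of the Bjellqvist charge model on pH in (0, 14).

    Net charge is monotone decreasing in pH, so bisection converges; the
    returned pH satisfies |net charge| < tol.
    """
    model = IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        charge = model.charge_at_pH(mid)
        if abs(charge) < tol:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
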