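"""Named protein motifs, promoter cis-elements, and GO bookkeeping.

Protein motifs use a small pattern language: plain residues, ``[...]``
position alternatives, and ``x`` for any residue (e.g. the plant-specific
DNA-binding motif ``[QRK]ALGGH``, the EAR repression motif ``[LF]DLN[LF]xP``
and the leucine-rich L-box ``ExExxAxCLxxL``).

Promoter scanning matches IUPAC nucleotide consensi on both strands of a
1500-bp upstream window and tallies hits by functional class (hormone,
stress, growth, core, other). GO utilities partition annotated transcripts
into the seven Venn regions of the MF/BP/CC primary categories and test
level-2 subcategory enrichment against a background transcriptome with a
Pearson chi-square (1 df, no continuity correction).
"""

from __future__ import annotations

import importlib.resources
import re
import warnings
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from scipy import stats

from .types import (
    AlphabetError,
    CisElement,
    EnrichmentResult,
    GoAnnotation,
    MotifDefinition,
    ParameterError,
    SequenceRecord,
)

PROMOTER_WINDOW = 1500  # bp of upstream sequence expected per promoter

#: conserved motifs of the C2H2-ZFP family, by their field names
NAMED_MOTIFS = [
    MotifDefinition("QALGGH", "[QRK]ALGGH"),
    MotifDefinition("EAR", "[LF]DLN[LF]xP"),
    MotifDefinition("L-box", "ExExxAxCLxxL"),
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def motif_regex(pattern: str) -> re.Pattern:
    """Compile a residue pattern ([..] alternatives, x wildcard) to regex."""
    out, i = [], 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            out.append(pattern[i : j + 1])
            i = j + 1
        elif ch in ("x", "X"):
            out.append(".")
            i += 1
        else:
            out.append(re.escape(ch.upper()))
            i += 1
    return re.compile("".join(out))


def scan_named_motifs(
    protein: SequenceRecord, motifs: Sequence[MotifDefinition] = NAMED_MOTIFS
) -> List[Tuple[str, int, str]]:
    """All motif occurrences as (motif name, 1-based start, matched text).

    Matches of different motifs may overlap; within one motif the scan is
    greedy left-to-right (non-overlapping). Results sorted by start, then
    motif name.
    """
    if protein.alphabet != "protein":
        raise AlphabetError(f"{protein.id!r}: protein sequence required")
    hits = []
    for m in motifs:
        rx = motif_regex(m.pattern)
        for match in rx.finditer(protein.sequence):
            hits.append((m.name, match.start() + 1, match.group()))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


# --- cis-regulatory elements ----------------------------------------------

def load_cis_catalog(path=None) -> List[CisElement]:
    """Load the cis-element catalog TSV (name, consensus, class).

    Without ``path`` the bundled catalog of canonical PlantCARE-style
    consensi is used.
    """
    if path is None:
        ref = importlib.resources.files("famscan.data") / "cis_elements.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    entries = [
        CisElement(str(r["name"]), str(r["consensus"]).upper(),
                   str(r["functional_class"]))
        for _, r in df.iterrows()
    ]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate element names in cis catalog")
    return entries


def _iupac_regex(consensus: str) -> re.Pattern:
    try:
        return re.compile("".join(_IUPAC[c] for c in consensus))
    except KeyError as exc:
        raise ParameterError(f"non-IUPAC code in consensus {consensus!r}") from exc


def reverse_complement_consensus(consensus: str) -> str:
    return consensus.translate(_COMPLEMENT)[::-1]


def scan_cis_elements(
    promoter: SequenceRecord,
    catalog: Sequence[CisElement],
    search_both_strands: bool = True,
) -> Tuple[List[Tuple[str, int, int, str]], Dict[str, int]]:
    """Scan one promoter for every catalog consensus.

    Returns (hits, class_tallies). Each hit is (element name, 1-based
    start, end, strand '+'/'-') in forward-strand coordinates. The minus
    strand is scanned by matching the reverse-complemented consensus on the
    forward sequence; a palindromic consensus therefore yields one hit per
    genomic position (position-deduplicated, '+' reported).
    """
    if promoter.alphabet != "nucleotide":
        raise AlphabetError(f"{promoter.id!r}: nucleotide sequence required")
    if len(promoter) > PROMOTER_WINDOW:
        warnings.warn(
            f"promoter {promoter.id!r} is {len(promoter)} bp, longer than the "
            f"declared {PROMOTER_WINDOW}-bp upstream window; scanning anyway",
            stacklevel=2,
        )
    seq = promoter.sequence
    hits: List[Tuple[str, int, int, str]] = []
    for element in catalog:
        spans = {}  # (start, end) -> strand, '+' wins for palindromes
        rx = _iupac_regex(element.consensus)
        pos = 0
        while True:
            m = rx.search(seq, pos)
            if m is None:
                break
            spans[(m.start() + 1, m.end())] = "+"
            pos = m.start() + 1  # overlapping occurrences allowed
        if search_both_strands:
            rc = reverse_complement_consensus(element.consensus)
            if rc != element.consensus:
                rx_rc = _iupac_regex(rc)
                pos = 0
                while True:
                    m = rx_rc.search(seq, pos)
                    if m is None:
                        break
                    spans.setdefault((m.start() + 1, m.end()), "-")
                    pos = m.start() + 1
        for (s, e), strand in spans.items():
            hits.append((element.name, s, e, strand))
    hits.sort(key=lambda h: (h[1], h[0]))
    by_class = {e.name: e.functional_class for e in catalog}
    tallies: Dict[str, int] = {}
    for name, *_ in hits:
        cls = by_class[name]
        tallies[cls] = tallies.get(cls, 0) + 1
    return hits, tallies


# --- GO bookkeeping --------------------------------------------------------

VENN_REGIONS = ("MF", "BP", "CC", "MF&BP", "MF&CC", "BP&CC", "MF&BP&CC")


def go_venn(
    annotations: Iterable[GoAnnotation],
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Partition annotated transcripts into the 7 MF/BP/CC Venn regions.

    Each transcript is counted once, in the region matching the exact set
    of primary categories it carries. Returns (region counts, per-category
    totals); a category total is the sum of its four regions.
    """
    cats: Dict[str, set] = {}
    for ann in annotations:
        cats.setdefault(ann.transcript_id, set()).add(ann.primary_category)
    regions = {r: 0 for r in VENN_REGIONS}
    for members in cats.values():
        key = "&".join(c for c in ("MF", "BP", "CC") if c in members)
        regions[key] += 1
    totals = {
        c: sum(n for r, n in regions.items() if c in r.split("&"))
        for c in ("MF", "BP", "CC")
    }
    return regions, totals


def chi_square_enrichment(
    observed: Dict[str, int],
    background: Dict[str, int],
    fdr: bool = False,
) -> List[EnrichmentResult]:
    """Test each subcategory's share in the family against the background.

    For each subcategory a 2x2 table (in/out of subcategory x
    family/background) is tested with a Pearson chi-square, 1 df, no
    continuity correction; direction compares the observed family count
    with its expectation under the background proportion. Significance is
    flagged at 0.05 and 0.01 (inclusive); no multiple-testing correction by
    default (``fdr=True`` applies Benjamini-Hochberg to the flags).
    A table with any expected cell < 1 is reported with ``reliable=False``.
    """
    fam_total = sum(observed.values())
    bg_total = sum(background.values())
    if bg_total <= 0 or fam_total <= 0:
        raise ParameterError("family and background totals must be > 0")
    results = []
    for sub in sorted(set(observed) | set(background)):
        b = background.get(sub, 0)
        if b <= 0:
            raise ParameterError(
                f"background count for {sub!r} must be > 0 to test it"
            )
        a = observed.get(sub, 0)
        table = [[a, fam_total - a], [b, bg_total - b]]
        expected_a = fam_total * (b / bg_total)
        exp = stats.contingency.expected_freq(table)
        reliable = bool((exp >= 1.0).all())
        if a / fam_total == b / bg_total:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        if a > expected_a:
            direction = "up"
        elif a < expected_a:
            direction = "down"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                subcategory=sub,
                observed=a,
                expected=expected_a,
                chi_square=float(chi2),
                p_value=float(p),
                direction=direction,
                significance=_flag(p),
                reliable=reliable,
            )
        )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                r.subcategory, r.observed, r.expected, r.chi_square,
                r.p_value, r.direction, _flag(q), r.reliable,
            )
            for r, q in zip(results, adj)
        ]
    return results


def _flag(p: float) -> str:
    if p <= 0.01:
        return "p01"
    if p <= 0.05:
        return "p05"
    return "ns"
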