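"""Comparative genomics of a gene family across assemblies.

Covers four steps: filtering BLAST-style alignment tables at fixed
threshold profiles, pan/core family-size composition from a
presence/absence matrix, Nei-Gojobori (1986) Ka/Ks estimation on
pre-aligned CDS pairs with Jukes-Cantor correction, and duplication dating
via T = Ks / (2 * lambda), with lambda the synonymous substitution rate per
site per year (default 6.5e-9 for dicots).
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

from .types import (
    AlignmentRecord,
    KaKsResult,
    ParameterError,
    SaturationError,
    SelectionBand,
    SequenceRecord,
    ThresholdProfile,
)

DEFAULT_LAMBDA = 6.5e-9  # synonymous substitutions per site per year

_STOPS = set(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_BASES = "ACGT"


def _aa(codon: str) -> str:
    """Translate a codon; stops map to '*'."""
    return "*" if codon in _STOPS else _CODON_TO_AA[codon]


# --- alignment filtering and pan/core -------------------------------------

def filter_alignments(
    records: Iterable[AlignmentRecord], profile: ThresholdProfile
) -> List[AlignmentRecord]:
    """Keep records meeting all three thresholds (boundaries inclusive):
    identity >= min_identity, align_length >= min_cover_length and
    evalue <= max_evalue. Input order is preserved."""
    return [
        r
        for r in records
        if r.identity >= profile.min_identity
        and r.align_length >= profile.min_cover_length
        and r.evalue <= profile.max_evalue
    ]


def presence_matrix(
    records: Iterable[AlignmentRecord],
    assemblies: Optional[Sequence[str]] = None,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Boolean genes x assemblies presence matrix from (filtered) records.

    A gene is present in an assembly iff at least one record maps it there
    (query = gene, subject prefix up to the first ':' = assembly, or the
    whole subject id when there is no ':').
    """
    pairs = set()
    seen_genes, seen_asm = [], []
    for r in records:
        asm = r.subject_id.split(":", 1)[0]
        if r.query_id not in seen_genes:
            seen_genes.append(r.query_id)
        if asm not in seen_asm:
            seen_asm.append(asm)
        pairs.add((r.query_id, asm))
    gene_index = list(genes) if genes is not None else sorted(seen_genes)
    asm_index = list(assemblies) if assemblies is not None else sorted(seen_asm)
    mat = pd.DataFrame(False, index=gene_index, columns=asm_index, dtype=bool)
    for g, a in pairs:
        if g in mat.index and a in mat.columns:
            mat.loc[g, a] = True
    return mat


def pan_core(presence: pd.DataFrame) -> Tuple[int, int, int, Dict[str, int]]:
    """Pan/core composition of a presence matrix (genes x assemblies).

    Returns (pan, core, dispensable, regions): pan is the union size over
    assemblies, core the intersection size, dispensable the difference.
    For up to three assemblies ``regions`` holds every exclusive Venn
    region, keyed by '&'-joined assembly names; genes absent everywhere are
    not counted in any region.
    """
    if presence.shape[1] < 1 or presence.shape[0] < 1:
        raise ParameterError("presence matrix must have >= 1 gene and assembly")
    sets = {a: set(presence.index[presence[a]]) for a in presence.columns}
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    pan, core = len(union), len(inter)
    regions: Dict[str, int] = {}
    names = list(presence.columns)
    if len(names) <= 3:
        for k in range(1, len(names) + 1):
            for combo in itertools.combinations(names, k):
                inside = set.intersection(*(sets[a] for a in combo))
                outside = set().union(
                    *(sets[a] for a in names if a not in combo), set()
                )
                regions["&".join(combo)] = len(inside - outside)
    return pan, core, pan - core, regions


# --- NG86 Ka/Ks ------------------------------------------------------------

def _codon_site_counts(codon: str) -> Tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon.

    Each position contributes s/3 synonymous sites, where s of its three
    possible single-nucleotide changes preserve the amino acid; changes to
    or from stop codons count as nonsynonymous, so the two fractions always
    sum to 3 (the stated site-count invariant).
    """
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if _aa(mutant) == _aa(codon) and _aa(codon) != "*":
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _codon_pair_diffs(a: str, b: str) -> Tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts between
    two codons, averaging with equal weights over every minimal
    substitution pathway (orderings of the differing positions)."""
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = a
        syn = nonsyn = 0
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if _aa(nxt) == _aa(cur) and _aa(cur) != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        syn_total += syn
        nonsyn_total += nonsyn
        n_paths += 1
    return syn_total / n_paths, nonsyn_total / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ParameterError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise SaturationError(
            f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(
    cds_a: SequenceRecord,
    cds_b: SequenceRecord,
    band: SelectionBand = SelectionBand(),
    lambda_rate: float = DEFAULT_LAMBDA,
) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for a pre-aligned, gap-free CDS pair.

    Site counts are per-codon mutational opportunities averaged over the
    two sequences; differences in multi-hit codons are averaged over all
    minimal substitution pathways with equal weights; ps and pn receive the
    Jukes-Cantor correction. The ratio is undefined (None) when ks = 0.
    """
    for rec in (cds_a, cds_b):
        if rec.alphabet != "nucleotide":
            raise ParameterError(f"{rec.id!r}: CDS must be nucleotide")
    a, b = cds_a.sequence, cds_b.sequence
    if len(a) != len(b):
        raise ParameterError("CDS pair must be pre-aligned to equal length")
    if len(a) % 3 != 0 or len(a) == 0:
        raise ParameterError("CDS length must be a nonzero multiple of 3")
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    for c in codons_a + codons_b:
        if c in _STOPS:
            raise ParameterError("internal stop codon in CDS")

    sa = na = sb = nb = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s1, n1 = _codon_site_counts(ca)
        s2, n2 = _codon_site_counts(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
    syn_sites = (sa + sb) / 2.0
    nonsyn_sites = (na + nb) / 2.0

    syn_diffs = nonsyn_diffs = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = _codon_pair_diffs(ca, cb)
        syn_diffs += sd
        nonsyn_diffs += nd

    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else None
    mode = classify_selection(ratio, band)
    return KaKsResult(
        ka=ka,
        ks=ks,
        ratio=ratio,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_diffs,
        nonsyn_diffs=nonsyn_diffs,
        divergence_time_mya=divergence_time(ks, lambda_rate),
        selection_mode=mode,
    )


def divergence_time(ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Date a duplication in million years: T = Ks / (2 * lambda) * 1e-6."""
    if ks < 0:
        raise ParameterError("ks must be >= 0")
    if lambda_rate <= 0:
        raise ParameterError("lambda_rate must be > 0")
    return ks / (2.0 * lambda_rate) * 1e-6


def classify_selection(
    ratio: Optional[float], band: SelectionBand = SelectionBand()
) -> str:
    """Classify selection mode from Ka/Ks against a neutral band.

    Below the band (ratio < center - half_width) is purifying, inside the
    band (inclusive) neutral, above positive; an undefined ratio (ks = 0)
    is 'undefined'.
    """
    if ratio is None:
        return "undefined"
    lo = band.center - band.half_width
    hi = band.center + band.half_width
    if ratio < lo:
        return "purifying"
    if ratio <= hi:
        return "neutral"
    return "positive"


def best_reciprocal_pairs(
    records: Iterable[AlignmentRecord],
) -> List[Tuple[str, str]]:
    """Best-reciprocal pairing over (filtered) cross-species records.

    Each query's best subject is the record with highest identity, ties by
    lowest e-value then lexicographic subject id; a (query, subject) pair is
    kept when each is the other's best. Pairs are returned sorted.
    """
    best: Dict[str, AlignmentRecord] = {}
    for r in records:
        cur = best.get(r.query_id)
        key = (-r.identity, r.evalue, r.subject_id)
        if cur is None or key < (-cur.identity, cur.evalue, cur.subject_id):
            best[r.query_id] = r
    pairs = set()
    for q, r in best.items():
        back = best.get(r.subject_id)
        if back is not None and back.subject_id == q:
            pairs.add(tuple(sorted((q, r.subject_id))))
    return sorted(pairs)
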