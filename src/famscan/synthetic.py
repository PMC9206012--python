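"""Synthetic data generators with known ground truth.

Every pipeline stage is exercisable without real sequencing data: these
generators plant C2H2 fingers in proteins, controlled synonymous and
nonsynonymous differences in codon-sequence pairs, a co-expressed module in
an expression matrix, known fold changes in qPCR CT tables, and a known
presence/absence map in BLAST-style alignment tables. Each generator is a
pure function of its seed and returns the planted truth alongside the data.

The protein linker alphabet excludes Cys and His, so a generated protein
contains exactly its planted fingers and nothing else — scanner recall and
precision on this output are exactly 100% by construction.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

from .types import (
    AlignmentRecord,
    GenerationError,
    NON_CH_RESIDUES,
    ParameterError,
    SequenceRecord,
    SyntheticTruth,
)

_STOPS = set(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_SENSE_CODONS = sorted(_CODON_TO_AA)
_BASES = "ACGT"

#: study-shaped sample label sets: 14 tissues, 4 root ages, 42 genotypes
TISSUE_SAMPLES = tuple(f"tissue_{i:02d}" for i in range(1, 15))
AGE_SAMPLES = ("root_5y", "root_12y", "root_18y", "root_25y")
GENOTYPE_SAMPLES = tuple(f"S{i}" for i in range(1, 43))


# --- proteins with planted fingers ----------------------------------------

def generate_protein_with_fingers(
    n_fingers: int,
    spacer_plan: Optional[Sequence[Tuple[int, int, int, int]]] = None,
    linker_len: int = 20,
    seed: int = 0,
    seq_id: str = "synthetic_protein",
) -> Tuple[SequenceRecord, SyntheticTruth]:
    """Build a protein containing exactly ``n_fingers`` C2H2 fingers.

    ``spacer_plan`` gives one (x2, gap1, core, gap2) tuple per finger with
    x2 fixed at 2, gap1 in 2..4, core fixed at 12 and gap2 in 2..8; omitted
    entries are drawn uniformly from the valid ranges. Fingers are
    separated by linkers of ``linker_len`` residues drawn from the 18
    standard residues excluding C and H, so no spurious finger can arise.
    """
    if n_fingers < 0 or linker_len < 0:
        raise ParameterError("n_fingers and linker_len must be >= 0")
    rng = np.random.default_rng(seed)
    if spacer_plan is None:
        spacer_plan = [
            (2, int(rng.integers(2, 5)), 12, int(rng.integers(2, 9)))
            for _ in range(n_fingers)
        ]
    if len(spacer_plan) != n_fingers:
        raise ParameterError("spacer_plan length must equal n_fingers")
    for x2, gap1, core, gap2 in spacer_plan:
        if x2 != 2 or core != 12 or not (2 <= gap1 <= 4) or not (2 <= gap2 <= 8):
            raise ParameterError(
                f"spacer tuple ({x2},{gap1},{core},{gap2}) outside the "
                "pattern ranges (2, 2-4, 12, 2-8)"
            )

    def linker(k: int) -> str:
        return "".join(rng.choice(list(NON_CH_RESIDUES), size=k))

    parts: List[str] = [linker(linker_len)]
    pos = linker_len  # 0-based length so far
    truth = SyntheticTruth()
    for x2, gap1, core, gap2 in spacer_plan:
        finger = (
            linker(x2) + "C" + linker(gap1) + "C" + linker(core)
            + "H" + linker(gap2) + "H"
        )
        start = pos + 1  # 1-based
        pos += len(finger)
        truth.planted_finger_positions.append((seq_id, start, pos))
        parts.append(finger)
        parts.append(linker(linker_len))
        pos += linker_len
    record = SequenceRecord(seq_id, "".join(parts), "protein")
    return record, truth


def plant_motif(
    protein: SequenceRecord,
    motif_text: str,
    position: int,
    motif_name: str,
    truth: SyntheticTruth,
) -> SequenceRecord:
    """Overwrite ``motif_text`` into a protein at a 1-based position and
    record it in the truth sidecar (for named-motif scanner tests)."""
    seq = protein.sequence
    if position < 1 or position + len(motif_text) - 1 > len(seq):
        raise ParameterError("motif does not fit at the requested position")
    new = seq[: position - 1] + motif_text + seq[position - 1 + len(motif_text):]
    truth.planted_motif_labels.append((protein.id, motif_name, position))
    return SequenceRecord(protein.id, new, "protein")


# --- paralogous CDS pairs --------------------------------------------------

def _single_nt_changes(codon: str):
    for i in range(3):
        for b in _BASES:
            if b != codon[i]:
                yield i, codon[:i] + b + codon[i + 1 :]


def generate_paralog_pair(
    n_codons: int,
    n_syn: int,
    n_nonsyn: int,
    seed: int = 0,
    max_retries: int = 200,
) -> Tuple[SequenceRecord, SequenceRecord, SyntheticTruth]:
    """A CDS and a derived paralog differing by exactly ``n_syn``
    synonymous and ``n_nonsyn`` nonsynonymous single-nucleotide changes.

    Changes are placed in distinct codons (so pathway averaging downstream
    is unambiguous), never create a stop codon, and the ancestral sequence
    is stop-free. Raises GenerationError if a requested change cannot be
    placed after bounded retries.
    """
    if n_codons < 1:
        raise ParameterError("n_codons must be >= 1")
    if n_syn < 0 or n_nonsyn < 0 or n_syn + n_nonsyn > n_codons:
        raise ParameterError("need n_codons >= n_syn + n_nonsyn, both >= 0")
    rng = np.random.default_rng(seed)
    codons = [ _SENSE_CODONS[i]
               for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons) ]
    derived = list(codons)
    free = list(range(n_codons))
    rng.shuffle(free)

    def place(synonymous: bool) -> None:
        for _ in range(max_retries):
            if not free:
                break
            idx = free.pop()
            codon = codons[idx]
            options = []
            for _, mutant in _single_nt_changes(codon):
                if mutant in _STOPS:
                    continue
                same = _CODON_TO_AA[mutant] == _CODON_TO_AA[codon]
                if same == synonymous:
                    options.append(mutant)
            if options:
                derived[idx] = options[int(rng.integers(0, len(options)))]
                return
            # codon admits no such change (e.g. ATG/TGG for synonymous):
            # leave it out of the free pool and retry with another codon
        raise GenerationError(
            f"could not place a {'synonymous' if synonymous else 'nonsynonymous'}"
            " change within the retry budget"
        )

    for _ in range(n_syn):
        place(True)
    for _ in range(n_nonsyn):
        place(False)

    seq_a = SequenceRecord("paralog_a", "".join(codons), "nucleotide")
    seq_b = SequenceRecord("paralog_b", "".join(derived), "nucleotide")
    truth = SyntheticTruth(n_syn=n_syn, n_nonsyn=n_nonsyn)
    return seq_a, seq_b, truth


def generate_pair_with_ks(
    n_codons: int, target_ks: float, seed: int = 0
) -> Tuple[SequenceRecord, SequenceRecord, SyntheticTruth]:
    """A paralog pair whose synonymous divergence targets ``target_ks``.

    The number of planted synonymous changes is chosen so that the
    Jukes-Cantor-corrected proportion of synonymous differences equals the
    target: n_syn = round(S * 3/4 * (1 - exp(-4 Ks / 3))) with S the pair's
    synonymous site count. The realised truth (after rounding) is stored in
    ``true_ks``.
    """
    if not (0 <= target_ks):
        raise ParameterError("target_ks must be >= 0")
    # two-pass: generate once to measure S, then plant the matching n_syn
    from .comparative import ng86_kaks

    probe_a, probe_b, _ = generate_paralog_pair(n_codons, 0, 0, seed=seed)
    syn_sites = ng86_kaks(probe_a, probe_b).syn_sites
    p_target = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    n_syn = int(round(p_target * syn_sites))
    a, b, truth = generate_paralog_pair(n_codons, n_syn, 0, seed=seed)
    # realised divergence after rounding; site count re-measured on the
    # planted pair because synonymous changes can shift codon degeneracy
    pair_sites = ng86_kaks(a, b).syn_sites
    realised_p = n_syn / pair_sites
    truth.true_ks = -0.75 * math.log(1.0 - 4.0 * realised_p / 3.0) \
        if n_syn else 0.0
    return a, b, truth


# --- expression matrices ---------------------------------------------------

def generate_expression_matrix(
    n_family: int,
    n_background: int,
    samples: Sequence[str] = GENOTYPE_SAMPLES,
    module_correlation: float = 0.9,
    seed: int = 0,
    scale: float = 2.0,
    shift: float = 10.0,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Transcripts x samples matrix with a planted co-expressed module.

    Family rows load on one shared latent factor with loading
    sqrt(module_correlation), so the expected pairwise Pearson correlation
    within the family equals ``module_correlation``; background rows are
    independent Gaussian noise. Values are affinely mapped to a nonnegative
    TPM-like scale (affine maps preserve correlations; the clip at zero is
    several SDs out and essentially never binds).
    """
    if len(samples) < 3:
        raise ParameterError("need >= 3 samples")
    if not (0.0 < module_correlation < 1.0):
        raise ParameterError("module_correlation must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_samples = len(samples)
    latent = rng.standard_normal(n_samples)
    lam = math.sqrt(module_correlation)
    rows = []
    ids = []
    for i in range(n_family):
        noise = rng.standard_normal(n_samples)
        rows.append(lam * latent + math.sqrt(1.0 - module_correlation) * noise)
        ids.append(f"fam_{i:04d}")
    for i in range(n_background):
        rows.append(rng.standard_normal(n_samples))
        ids.append(f"bg_{i:04d}")
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, n_samples))
    values = np.clip(values * scale + shift, 0.0, None)
    matrix = pd.DataFrame(values, index=ids, columns=list(samples))
    truth = SyntheticTruth(
        true_module_members=set(ids[:n_family]),
        true_module_correlation=module_correlation,
    )
    return matrix, truth


# --- qPCR CT tables --------------------------------------------------------

def generate_qpcr_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    fold_changes: Dict[str, Dict[str, float]],
    reference_gene: str,
    calibrator_condition: Optional[str] = None,
    n_reps: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """CT table (gene, condition, replicate, ct) with planted fold changes.

    For a gene with fold change f in a condition, its mean CT there is the
    gene's baseline minus log2(f) (reference gene CT is condition-invariant),
    so the expected ddCT relative to the calibrator is -log2(f). The
    reference gene must have fold change 1 in every condition. Replicate
    noise is i.i.d. Gaussian with SD ``noise_sd`` cycles.
    """
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")
    if reference_gene not in genes:
        raise ParameterError(f"reference gene {reference_gene!r} not in genes")
    if calibrator_condition is None:
        calibrator_condition = conditions[0]
    for g in genes:
        for c in conditions:
            f = fold_changes.get(g, {}).get(c, 1.0)
            if f <= 0:
                raise ParameterError("fold changes must be > 0")
            if g == reference_gene and f != 1.0:
                raise ParameterError("reference gene must have fold change 1")
            if c == calibrator_condition and f != 1.0:
                raise ParameterError("calibrator condition must have fold 1")
    rng = np.random.default_rng(seed)
    base_ct = {g: float(rng.uniform(20.0, 26.0)) for g in genes}
    rows = []
    for g in genes:
        for c in conditions:
            f = fold_changes.get(g, {}).get(c, 1.0)
            mean_ct = base_ct[g] - math.log2(f)
            for rep in range(1, n_reps + 1):
                ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((g, c, rep, ct))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    truth = SyntheticTruth(
        true_fold_changes={
            g: {c: fold_changes.get(g, {}).get(c, 1.0) for c in conditions}
            for g in genes
        }
    )
    return table, truth


# --- alignment tables ------------------------------------------------------

def generate_alignment_table(
    gene_ids: Sequence[str],
    presence: Dict[str, Set[str]],
    seed: int = 0,
) -> Tuple[List[AlignmentRecord], SyntheticTruth]:
    """BLAST outfmt-6 style records realising a known presence map.

    Present genes get a record passing the within-species profile
    (identity >= 99, length >= 200, e <= 1e-100); absent genes get either
    no record or a decoy failing at least one threshold, so filtering at
    that profile recovers the presence map exactly.
    """
    rng = np.random.default_rng(seed)
    records: List[AlignmentRecord] = []
    for assembly in sorted(presence):
        present = presence[assembly]
        unknown = present - set(gene_ids)
        if unknown:
            raise ParameterError(f"presence names unknown genes: {sorted(unknown)}")
        for gene in gene_ids:
            if gene in present:
                length = int(rng.integers(200, 801))
                records.append(
                    AlignmentRecord(
                        query_id=gene,
                        subject_id=f"{assembly}:ctg{int(rng.integers(1, 25)):02d}",
                        identity=float(np.round(rng.uniform(99.0, 100.0), 2)),
                        align_length=length,
                        query_start=1, query_end=length,
                        subject_start=1, subject_end=length,
                        evalue=0.0,
                        bit_score=float(np.round(rng.uniform(300, 1500), 1)),
                    )
                )
            else:
                mode = int(rng.integers(0, 4))
                if mode == 0:
                    continue  # absent: no record at all
                identity = float(np.round(rng.uniform(99.0, 100.0), 2))
                length = int(rng.integers(200, 801))
                evalue = 0.0
                if mode == 1:
                    identity = float(np.round(rng.uniform(80.0, 98.9), 2))
                elif mode == 2:
                    length = int(rng.integers(30, 200))
                else:
                    evalue = 10.0 ** float(rng.uniform(-99, -20))
                records.append(
                    AlignmentRecord(
                        query_id=gene,
                        subject_id=f"{assembly}:ctg{int(rng.integers(1, 25)):02d}",
                        identity=identity,
                        align_length=length,
                        query_start=1, query_end=length,
                        subject_start=1, subject_end=length,
                        evalue=evalue,
                        bit_score=float(np.round(rng.uniform(30, 300), 1)),
                    )
                )
    truth = SyntheticTruth(presence={a: set(g) for a, g in presence.items()})
    return records, truth


# --- promoters with planted cis elements -----------------------------------

def generate_promoter_with_elements(
    elements: Sequence[Tuple[str, str, int]],
    length: int = 1500,
    seed: int = 0,
    seq_id: str = "synthetic_promoter",
) -> Tuple[SequenceRecord, SyntheticTruth]:
    """A promoter of ``length`` bp with consensus sites written in at known
    positions. ``elements`` is (element name, concrete site sequence,
    1-based start). Background is uniform random ACGT; the caller is
    responsible for choosing positions that do not overlap."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    truth = SyntheticTruth()
    for name, site, start in elements:
        if start < 1 or start + len(site) - 1 > length:
            raise ParameterError(f"site {name!r} does not fit at {start}")
        seq[start - 1 : start - 1 + len(site)] = list(site.upper())
        truth.planted_motif_labels.append((seq_id, name, start))
    return SequenceRecord(seq_id, "".join(seq), "nucleotide"), truth
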