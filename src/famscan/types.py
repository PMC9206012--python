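"""Shared domain types for the gene-family analysis pipeline.

Coordinate convention: 1-based, inclusive, throughout (protein residue
coordinates and nucleotide coordinates alike).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

#: the 18 standard residues excluding Cys and His (safe linker alphabet for
#: synthetic proteins: cannot create a spurious C2H2 finger)
NON_CH_RESIDUES = "ADEFGIKLMNPQRSTVWY"


class AlphabetError(ValueError):
    """Raised when a sequence of the wrong alphabet is supplied."""


class ParameterError(ValueError):
    """Raised when an argument violates its documented range."""


class GenerationError(RuntimeError):
    """Raised when a synthetic generator cannot satisfy its constraints."""


class SaturationError(ValueError):
    """Raised when an observed proportion of differences exceeds the
    Jukes-Cantor correction domain (p >= 3/4)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with an alphabet tag.

    ``alphabet`` is ``"nucleotide"`` (ACGTN) or ``"protein"`` (20 standard
    residues plus X). Sequences are stored uppercase.
    """

    id: str
    sequence: str
    alphabet: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParameterError("SequenceRecord id must be nonempty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.alphabet == "protein":
            bad = set(self.sequence) - PROTEIN_ALPHABET
        elif self.alphabet == "nucleotide":
            bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        else:
            raise ParameterError(f"unknown alphabet {self.alphabet!r}")
        if bad:
            raise ParameterError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ZincFingerHit:
    """One C2H2 zinc-finger match (pattern X2-C-X2..4-C-X12-H-X2..8-H).

    ``start``/``end`` are 1-based inclusive residue coordinates; the four
    anchor residues inside ``matched_subsequence`` are C, C, H, H.
    """

    sequence_id: str
    start: int
    end: int
    gap1_len: int
    gap2_len: int
    matched_subsequence: str

    def __post_init__(self) -> None:
        expected = 2 + 1 + self.gap1_len + 1 + 12 + 1 + self.gap2_len + 1
        if self.end - self.start + 1 != expected:
            raise ParameterError("zinc-finger hit length inconsistent with gaps")
        if not (2 <= self.gap1_len <= 4 and 2 <= self.gap2_len <= 8):
            raise ParameterError("gap lengths outside the C2H2 pattern ranges")


@dataclass(frozen=True)
class ProteinProperties:
    """ProtParam-style physicochemical summary of one protein."""

    molecular_weight: float  # Da, average isotopic masses
    isoelectric_point: float  # pH units
    gravy: float  # grand average of hydropathicity (Kyte-Doolittle)
    instability_index: float  # Guruprasad DIWV statistic
    aliphatic_index: float  # Ikai
    is_hydrophilic: bool  # gravy < 0
    is_unstable: bool  # instability_index > 40


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame located on either strand of a transcript.

    Coordinates are 1-based inclusive on the forward strand; ``frame`` is
    one of +1, +2, +3, -1, -2, -3. ``partial`` marks ORFs that run off the
    sequence end without a stop codon.
    """

    sequence_id: str
    frame: int
    start: int
    end: int
    protein: str
    partial: bool = False


@dataclass(frozen=True)
class AlignmentRecord:
    """One BLAST outfmt-6 style alignment row (query vs assembly)."""

    query_id: str
    subject_id: str
    identity: float  # percent
    align_length: int  # bp
    mismatches: int = 0
    gap_opens: int = 0
    query_start: int = 1
    query_end: int = 1
    subject_start: int = 1
    subject_end: int = 1
    evalue: float = 0.0
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ParameterError(f"identity {self.identity} outside [0, 100]")
        if self.align_length < 1:
            raise ParameterError("align_length must be >= 1")
        if self.evalue < 0:
            raise ParameterError("evalue must be >= 0")


@dataclass(frozen=True)
class ThresholdProfile:
    """Alignment acceptance thresholds (all boundaries inclusive)."""

    min_identity: float
    min_cover_length: int
    max_evalue: float
    name: str = "custom"


#: within-species gene-to-assembly mapping profile
WITHIN_SPECIES = ThresholdProfile(99.0, 200, 1.0e-100, "within_species")
#: cross-species (distant relative) mapping profile
CROSS_SPECIES = ThresholdProfile(75.0, 80, 1.0e-10, "cross_species")


@dataclass(frozen=True)
class KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks estimate for one pre-aligned CDS pair."""

    ka: float
    ks: float
    ratio: Optional[float]  # None when ks == 0
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    divergence_time_mya: float
    selection_mode: str  # purifying | neutral | positive | undefined


@dataclass(frozen=True)
class SelectionBand:
    """Neutral band around Ka/Ks = 1 used to classify selection mode."""

    center: float = 1.0
    half_width: float = 0.1

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ParameterError("half_width must be > 0")


@dataclass(frozen=True)
class MotifDefinition:
    """A named residue motif with [..] alternatives and x wildcards."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ParameterError("motif pattern must be nonempty")


@dataclass(frozen=True)
class CisElement:
    """One promoter cis-regulatory element consensus (IUPAC nucleotides)."""

    name: str
    consensus: str
    functional_class: str  # hormone | stress | growth | core | other


@dataclass(frozen=True)
class GoAnnotation:
    """One transcript-to-GO assignment (flat level-2 subcategory label)."""

    transcript_id: str
    primary_category: str  # MF | BP | CC
    level2_subcategory: str

    def __post_init__(self) -> None:
        if self.primary_category not in ("MF", "BP", "CC"):
            raise ParameterError(
                f"unknown GO primary category {self.primary_category!r}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Chi-square enrichment of one subcategory vs a background set."""

    subcategory: str
    observed: int
    expected: float
    chi_square: float
    p_value: float
    direction: str  # up | down | none
    significance: str  # ns | p05 | p01
    reliable: bool = True  # False when an expected cell < 1


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation of one unordered transcript pair (id_a < id_b)."""

    id_a: str
    id_b: str
    r: float
    t_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class HubCriteria:
    """Hub-gene criteria: network P cutoff, minimum connectivity, and the
    maximum fraction of network nodes that may be called hubs."""

    network_p_cutoff: float = 0.001
    min_connectivity: int = 30
    max_hub_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.network_p_cutoff <= 0 or self.min_connectivity <= 0:
            raise ParameterError("hub criteria must be positive")
        if not (0 < self.max_hub_fraction <= 1):
            raise ParameterError("max_hub_fraction must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    planted_finger_positions: list = field(default_factory=list)
    planted_motif_labels: list = field(default_factory=list)
    true_module_members: set = field(default_factory=set)
    true_module_correlation: Optional[float] = None
    true_fold_changes: dict = field(default_factory=dict)
    true_ka: Optional[float] = None
    true_ks: Optional[float] = None
    n_syn: Optional[int] = None
    n_nonsyn: Optional[int] = None
    presence: dict = field(default_factory=dict)
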