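# Methods

This note documents the models and procedures `famscan` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Finger pattern scanning

The family-defining domain is matched literally as
X₂-C-X(2,4)-C-X₁₂-H-X(2,8)-H on the 20-residue alphabet (X = any residue).
The core between the second cysteine and the first histidine is fixed at
12 residues; only the Cys spacer (gap1, 2–4) and His spacer (gap2, 2–8)
vary. The scan is greedy left-to-right: at each candidate anchor the
shortest valid gap1 is tried first, then the shortest valid gap2, and
after a hit the scan resumes at the residue following the hit's second
histidine, so reported hits never overlap. This convention is a choice —
overlapping-candidate resolution is not standardised anywhere — and it is
pinned by `validate_hit`, an independent residue-by-residue checker used
in the tests. Family membership requires ≥ 1 finger (`min_fingers`,
default 1); plant C2H2-ZFP members typically carry one to six.

## ORF finding

All six frames are scanned; within a frame each stop-to-stop segment
yields at most one ORF, from its first ATG (the longest ORF in that
segment). An ORF reaching the sequence end without a stop is reported as
partial. Codons containing N never act as starts or stops and translate
to X. Coordinates are 1-based inclusive on the forward strand; minus-frame
spans are mapped back through the reverse complement. The default minimum
protein length is 25 aa — short enough to keep true zinc-finger ORFs,
long enough to suppress spurious micro-ORFs; examples in the tests pass
an explicit lower bound when exercising toy sequences.

## Protein properties

The ProtParam panel: molecular weight from average residue masses minus
peptide-bond water; GRAVY as mean Kyte–Doolittle hydropathy (negative =
hydrophilic); the Guruprasad instability index (10/L · Σ DIWV over
adjacent dipeptides; > 40 predicts in-vitro instability); Ikai's aliphatic
index 100·(xAla + 2.9·xVal + 3.9·(xIle + xLeu)); and the isoelectric point
by bisecting the Bjellqvist charge model on pH ∈ (0, 14) until
|net charge| < 10⁻⁴ (net charge is monotone in pH, so bisection converges
unconditionally). X residues are excluded from every metric, with mole
fractions renormalised over the remaining residues. The dipeptide weights
and charge model are taken from Biopython's ProtParam data; the tests
cross-check all four shared quantities against Biopython's independent
`ProteinAnalysis` implementation.

## Alignment filtering and pan/core composition

Two fixed threshold profiles: within-species (identity ≥ 99%, alignment
length ≥ 200 bp, e-value ≤ 1.0e-100) and cross-species (≥ 75%, ≥ 80 bp,
≤ 1.0e-10), all boundaries inclusive. "Cover length" is read as alignment
length in bp. A gene is present in an assembly iff at least one filtered
record maps it there; the pan set is the union over assemblies, the core
the intersection, the dispensable set their difference, with all exclusive
Venn regions enumerated for up to three assemblies. Filtering is
idempotent, order-preserving, and monotone in its thresholds (property
tests). Cross-species orthologue assignment is reduced to best-reciprocal
pairing over filtered records (highest identity, ties by lowest e-value,
then lexicographic subject id); full synteny-block detection is out of
scope.

## Ka/Ks (Nei–Gojobori 1986) and duplication dating

Input is a pre-aligned, gap-free, stop-free CDS pair. Synonymous site
counts are per-codon mutational opportunities (each position contributes
s/3 sites, where s of its three possible changes preserve the amino
acid), averaged over the two sequences; changes to or from stop codons
count as nonsynonymous, so syn + nonsyn sites = 3 × codons exactly.
Differences in codons differing at multiple positions are averaged over
all minimal substitution pathways with equal weights — the tests pin this
against a brute-force pathway enumeration that shares no code with the
implementation. Proportions receive the Jukes–Cantor correction
d = −¾·ln(1 − 4p/3); p ≥ ¾ raises a saturation error rather than
returning a complex number. Ka/Ks is undefined when Ks = 0. Duplication
age is T = Ks/(2λ)·10⁻⁶ MYA with λ = 6.5 × 10⁻⁹ synonymous
substitutions/site/year (a standard dicot rate, overridable). Selection
mode uses a neutral band of 1.0 ± 0.1, boundaries inclusive: < 0.9
purifying, 0.9–1.1 neutral, > 1.1 positive.

At the divergences the dating targets (Ks ≤ 0.6), equal-weight pathway
averaging and the JC correction recover generated Ks within a few percent
(the acceptance budget allows 15% for the correction's small-sample
bias).

## Motif and cis-element scanning

Named protein motifs use a small pattern language (literal residues,
`[...]` alternatives, `x` wildcard); the shipped set is [QRK]ALGGH,
[LF]DLN[LF]xP (EAR) and ExExxAxCLxxL (L-box). Matches of different motifs
may overlap; within one motif matching is greedy left-to-right.

Promoter scanning expects 1500-bp upstream windows (longer input warns
and proceeds) and matches IUPAC consensi exactly, with overlaps allowed.
The minus strand is scanned by matching the reverse-complemented
consensus on the forward sequence; hits are reported in forward
coordinates and deduplicated by span, so a palindromic consensus counts
once per genomic position. The bundled catalog holds ~25 canonical
PlantCARE-style elements mapped to hormone/stress/growth/core/other
classes; real studies distinguish ~50 element types, so the catalog is an
editable TSV, not an exhaustive registry.

## GO bookkeeping and enrichment

Each annotated transcript is counted once in exactly one of the seven
MF/BP/CC Venn regions, by the set of primary categories it carries;
category totals are sums of four regions, and the regions partition the
annotated transcripts (property test). Enrichment of a level-2
subcategory compares family vs background with a 2×2 Pearson chi-square
(1 df, no Yates correction — expected counts in this setting are large),
flagged at P ≤ 0.05 and P ≤ 0.01. No multiple-testing correction is
applied by default, matching common practice in gene-family surveys; a
Benjamini–Hochberg option exists. Tables with an expected cell < 1 are
reported but flagged unreliable. "Level 2" is a flat label supplied by
the annotation table; GO DAG traversal is out of scope.

## Co-expression networks

For transcripts × samples matrices (≥ 3 samples; zero-variance rows are
dropped with a warning), every unordered pair gets Pearson r and a
two-sided P from t = r·√((n−2)/(1−r²)) on n−2 df (|r| = 1 ⇒ P = 0). An
edge joins pairs with P ≤ cutoff; nodes are transcripts incident to ≥ 1
edge, so node counts vary with the cutoff, and edge sets are nested along
the descending default series 5e-2, 1e-2, … 1e-8. Clusters are connected
components (deterministic labels by smallest member id); heavier module
detection (MCL, WGCNA) is out of scope. Hub genes come from the P ≤ 0.001
network: degree ≥ 30, capped at floor(5% of nodes) by degree with
lexicographic tie-break.

### Tendency test

Whether a family forms a denser network than chance: per replicate
(default 20), equal-size subsamples are drawn without replacement from
the family matrix and from a background pool; networks are built at every
cutoff; per cutoff, family vs control node and edge counts are compared
with a two-sided Student's t-test (Welch optional). The default compares
the full family against size-matched controls; subsampling the family
itself is available via `subsample_size`.

**Calibration caveat.** The t-test treats replicates as independent. That
holds when the subsample is small relative to both pools (controls drawn
fresh from a large transcriptome database — the regime the acceptance
suite verifies: null rejection 0.05 ± 0.02 over 200 runs). When
subsamples overlap heavily (e.g. drawing 176 of a 228-transcript family),
replicate counts are strongly dependent, replicate variance understates
pool-level sampling noise, and the test becomes anticonservative under
the null (measured ~0.49 rejection when subsampling 15 of a 20-row pool).
Power on real modules is unaffected; null P values from
heavily-overlapping designs should not be read at face value.

## qPCR quantification

ΔCT(gene, condition) = mean CT(gene) − mean CT(reference) within the
condition; ΔΔCT subtracts the calibrator condition's ΔCT; fold = 2^−ΔΔCT
(amplification efficiency fixed at 2; efficiency correction out of
scope). Per-replicate ΔCT values (replicate CT minus the condition's mean
reference CT) feed a two-sample t-test of each condition against the
calibrator, flagged at 0.05/0.01. Fold changes are invariant to a
constant CT offset per condition (machine drift), and the reference
gene's own fold is 1 everywhere by construction.

## Synthetic generators

All generators are pure functions of their seed. What they emulate, and
what they deliberately do not:

- **Proteins.** Planted fingers with exact spacer plans, separated by
  linkers drawn from the 18 residues excluding C and H — so no spurious
  finger can arise and scanner recall/precision are exactly 100% by
  construction. Real proteins of course contain free cysteines and
  histidines; the exactness claim is about the scanner's logic, not about
  false-positive rates on natural sequence.
- **Paralog pairs.** A stop-free random CDS and a derived copy differing
  by exactly the requested number of synonymous and nonsynonymous
  single-nucleotide changes, one per codon (keeping pathway averaging
  unambiguous), never creating stops. Real paralogs accumulate multi-hit
  codons, indels and selection heterogeneity that this fixture
  intentionally lacks; `generate_pair_with_ks` targets a Ks by inverting
  the JC correction against the pair's measured synonymous site count.
- **Expression.** Family rows share one latent Gaussian factor with
  loading √ρ (expected pairwise Pearson r = ρ, default 0.9); background
  rows are independent. Values are affinely mapped to a nonnegative
  TPM-like scale (shift 10, scale 2) — affine maps preserve correlations
  and the zero-clip is ~5 SD out. Sample label sets mirror the study
  shapes (14 tissues, 4 root ages, 42 genotypes). Real expression is
  heteroskedastic, zero-inflated, and mean-variance coupled; passing
  tests show statistic correctness, not robustness to those features.
- **qPCR.** Gene baselines ~U(20, 26) cycles, condition means shifted by
  −log₂(fold), i.i.d. Gaussian replicate noise (default SD 0.1 cycles,
  3 replicates), condition-invariant reference gene.
- **Alignment tables.** Present genes get records sampling the passing
  region (identity 99–100, length 200–800, e = 0); absent genes get
  nothing or a decoy failing exactly one randomly chosen threshold —
  filtering at the within-species profile recovers the presence map
  exactly.

## Problem sizes

The bundled pipeline fixture uses 24 family proteins (1–6 fingers each)
plus 6 fingerless decoys, 10 CDS pairs of 200 codons, a 3-assembly
presence map over 24 genes, a 40-transcript module at ρ = 0.9 with a
120-row background over 42 samples, 2,120 GO rows, 8 promoters of
1500 bp, and a 5-gene × 4-dose CT table. The acceptance script scales the
statistical checks to 500 oracle codon pairs, 12 Ks targets at 400
codons, 20 qPCR seeds, 10,000 correlation pairs, and 200 null tendency
runs — sizes at which the Monte-Carlo bands quoted above are comfortably
resolved.

## Known limitations

- The pattern classifier replaces profile-HMM scoring; degenerate fingers
  with non-canonical core lengths (X ≠ 12) are not matched.
- NG86 with equal-weight pathways and JC correction is the classic
  estimator; it ignores transition/transversion bias and codon-frequency
  effects (ML-style estimators are out of scope) and saturates near
  p = 3/4.
- The cis-element catalog is a curated approximation, not a PlantCARE
  mirror.
- Connected components stand in for model-based clustering of networks.
- The tendency test's null calibration depends on the subsample-to-pool
  ratio (see above).
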