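"""Co-expression networks, hub genes, and the network-formation tendency test.

An edge joins two transcripts whose expression profiles across samples are
Pearson-correlated with a two-sided P (t distribution, n-2 df) at or below
a cutoff. Networks are rebuilt over a descending series of cutoffs (default
5e-2 down to 1e-8); edge sets are nested across that series. The tendency
test asks whether a gene family forms a denser network than size-matched
random transcript sets: per replicate it subsamples the family and a
control pool, builds both networks at every cutoff, and compares node and
edge counts with a two-sample Student's t-test.

Hub genes are the high-connectivity nodes of the P <= 0.001 network:
degree >= 30, capped at 5% of the network's nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import CorrelationRecord, HubCriteria, ParameterError

logger = logging.getLogger(__name__)

#: default cutoff series, descending (P <= 5.0E-02 down to 1.0E-08)
DEFAULT_CUTOFFS = (5e-2, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


@dataclass
class TendencyTestResult:
    """Replicate x cutoff node/edge counts for family vs control networks,
    with per-cutoff two-sample t statistics."""

    cutoffs: List[float]
    family_node_counts: np.ndarray  # (n_reps, n_cutoffs)
    family_edge_counts: np.ndarray
    control_node_counts: np.ndarray
    control_edge_counts: np.ndarray
    node_t_stats: List[float] = field(default_factory=list)
    node_p_values: List[float] = field(default_factory=list)
    edge_t_stats: List[float] = field(default_factory=list)
    edge_p_values: List[float] = field(default_factory=list)


def _clean_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance rows (cannot be correlated), with a warning."""
    values = matrix.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        logger.warning("excluding %d zero-variance rows: %s",
                       len(dropped), dropped[:5])
        matrix = matrix.loc[keep]
    return matrix


def _pvalue_matrices(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided P for every row pair of ``values``.

    P comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 df; |r| = 1 maps to P = 0.
    """
    n = values.shape[1]
    if n < 3:
        raise ParameterError("need >= 3 samples for correlation P-values")
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    np.fill_diagonal(p, 1.0)
    return r, p


def correlation_pvalues(matrix: pd.DataFrame) -> List[CorrelationRecord]:
    """Pearson r with two-sided P for every unordered transcript pair.

    ``matrix`` is transcripts x samples; zero-variance rows are excluded
    with a logged warning. Pairs are stored once with id_a < id_b.
    """
    matrix = _clean_matrix(matrix)
    ids = [str(i) for i in matrix.index]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate transcript ids")
    values = matrix.to_numpy(dtype=float)
    n = matrix.shape[1]
    r, p = _pvalue_matrices(values)
    t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = sorted((ids[i], ids[j]))
            records.append(
                CorrelationRecord(
                    id_a=a, id_b=b, r=float(r[i, j]),
                    t_stat=float(t[i, j]), p_value=float(p[i, j]), n=n,
                )
            )
    return records


def build_network(
    records: Iterable[CorrelationRecord], p_cutoff: float
) -> nx.Graph:
    """Graph with an edge for every pair with P <= cutoff.

    Nodes are transcripts incident to at least one edge; transcripts that
    correlate with nothing at the cutoff do not appear, so node counts vary
    with the cutoff.
    """
    if not (0 <= p_cutoff < 1):
        raise ParameterError("p_cutoff must be in [0, 1)")
    g = nx.Graph()
    for rec in records:
        if rec.p_value <= p_cutoff and rec.id_a != rec.id_b:
            g.add_edge(rec.id_a, rec.id_b, r=rec.r, p=rec.p_value)
    return g


def connected_components(g: nx.Graph) -> Tuple[Dict[str, str], int]:
    """Label every node with its component, named by its smallest member id.

    Returns (node -> label, component count)."""
    labels: Dict[str, str] = {}
    count = 0
    for comp in nx.connected_components(g):
        count += 1
        label = min(comp)
        for node in comp:
            labels[node] = label
    return labels, count


def hub_genes(
    records: Iterable[CorrelationRecord],
    criteria: HubCriteria = HubCriteria(),
) -> List[Tuple[str, int]]:
    """Hub genes of the network built at the criteria's P cutoff.

    Candidates are nodes with degree >= min_connectivity; when they exceed
    max_hub_fraction of the network's nodes only the top
    floor(fraction * nodes) by degree are kept (ties by lexicographic id).
    Returns (gene, connectivity) sorted by degree descending, then id.
    """
    g = build_network(records, criteria.network_p_cutoff)
    candidates = [(node, d) for node, d in g.degree() if d >= criteria.min_connectivity]
    candidates.sort(key=lambda x: (-x[1], x[0]))
    cap = math.floor(criteria.max_hub_fraction * g.number_of_nodes())
    if len(candidates) > cap:
        candidates = candidates[:cap]
    return candidates


def _counts_at_cutoffs(
    p: np.ndarray, cutoffs: Sequence[float]
) -> Tuple[List[int], List[int]]:
    """Node and edge counts of the thresholded graph at each cutoff
    (nodes = rows incident to >= 1 edge)."""
    iu = np.triu_indices(p.shape[0], k=1)
    pv = p[iu]
    nodes, edges = [], []
    for c in cutoffs:
        mask = pv <= c
        edges.append(int(mask.sum()))
        adj = np.zeros(p.shape, dtype=bool)
        adj[iu[0][mask], iu[1][mask]] = True
        adj |= adj.T
        nodes.append(int(adj.any(axis=1).sum()))
    return nodes, edges


def tendency_test(
    family_matrix: pd.DataFrame,
    background_matrix: pd.DataFrame,
    subsample_size: Optional[int] = None,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    n_reps: int = 20,
    seed: int = 0,
    equal_var: bool = True,
) -> TendencyTestResult:
    """Randomized-control test of a family's tendency to form a network.

    Per replicate, ``subsample_size`` rows are drawn without replacement
    from the family matrix and from the background matrix (size-matched
    control); networks are built at every cutoff and node/edge counts
    recorded. Per cutoff, family vs control counts over replicates are
    compared with a two-sided Student's t-test (equal variance by default;
    Welch via ``equal_var=False``). ``subsample_size=None`` uses the full
    family row count.
    """
    if list(family_matrix.columns) != list(background_matrix.columns):
        raise ParameterError("family and background must share sample columns")
    if subsample_size is None:
        subsample_size = family_matrix.shape[0]
    if subsample_size > family_matrix.shape[0] or subsample_size > background_matrix.shape[0]:
        raise ParameterError("subsample_size exceeds available rows")
    if subsample_size < 2:
        raise ParameterError("subsample_size must be >= 2")
    cutoffs = list(cutoffs)
    rng = np.random.default_rng(seed)
    fam = family_matrix.to_numpy(dtype=float)
    bg = background_matrix.to_numpy(dtype=float)
    shape = (n_reps, len(cutoffs))
    fam_nodes = np.zeros(shape, dtype=int)
    fam_edges = np.zeros(shape, dtype=int)
    ctl_nodes = np.zeros(shape, dtype=int)
    ctl_edges = np.zeros(shape, dtype=int)
    for rep in range(n_reps):
        fi = rng.choice(fam.shape[0], size=subsample_size, replace=False)
        bi = rng.choice(bg.shape[0], size=subsample_size, replace=False)
        _, pf = _pvalue_matrices(fam[fi])
        _, pb = _pvalue_matrices(bg[bi])
        fam_nodes[rep], fam_edges[rep] = _counts_at_cutoffs(pf, cutoffs)
        ctl_nodes[rep], ctl_edges[rep] = _counts_at_cutoffs(pb, cutoffs)
    result = TendencyTestResult(
        cutoffs=cutoffs,
        family_node_counts=fam_nodes,
        family_edge_counts=fam_edges,
        control_node_counts=ctl_nodes,
        control_edge_counts=ctl_edges,
    )
    for k in range(len(cutoffs)):
        tn, pn = _safe_ttest(fam_nodes[:, k], ctl_nodes[:, k], equal_var)
        te, pe = _safe_ttest(fam_edges[:, k], ctl_edges[:, k], equal_var)
        result.node_t_stats.append(tn)
        result.node_p_values.append(pn)
        result.edge_t_stats.append(te)
        result.edge_p_values.append(pe)
    return result


def _safe_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> Tuple[float, float]:
    if np.std(a) == 0 and np.std(b) == 0:
        # degenerate: identical constant counts -> no evidence either way
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.inf if np.mean(a) > np.mean(b) else -math.inf, 0.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
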