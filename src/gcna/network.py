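"""Seed-anchored co-expression networks and their comparison across strata.

Construction follows seven rules: (1) edges weighted by Spearman correlation;
(2) each non-seed gene keeps at most ``edge_limit`` edges, assigned greedily
from the highest correlation down; (3) genes are coloured by complete-linkage
hierarchical clusters on 1 - rho, cut at (max merge height)/1.5; (4) icon
size is the absolute coefficient of variation of expression; (5) seed genes
are diamonds, co-expressed genes circles, and significantly
recurrence-associated co-expressed genes stars; (6) icon frames are red for
0.01 <= p < 0.05 and yellow for p < 0.01; (7) up-regulated genes (higher mean
expression in recurrent cases) are drawn dashed, down-regulated solid.

Correlations, clustering and cv are computed within each stratum's samples;
the Cox p-values and up/down direction that annotate the nodes come from the
full cohort (a stratum defined by recurrence status has no event contrast of
its own).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .data import CohortStudy
from .survival import CoxResult, screen_genes

log = logging.getLogger(__name__)

NODE_ATTRS = ("cv", "cluster", "shape", "frame", "direction", "is_seed")


@dataclass(frozen=True)
class CandidateEdge:
    """A seed <-> non-seed gene pair with its Spearman correlation."""

    seed_gene: str
    partner_gene: str
    rho: float


@dataclass
class GeneNetwork:
    """An annotated co-expression network for one phenotype stratum."""

    graph: nx.Graph
    stratum: str
    seeds: frozenset[str]

    @property
    def nonseed_nodes(self) -> frozenset[str]:
        return frozenset(n for n in self.graph.nodes if n not in self.seeds)

    @property
    def seed_nodes(self) -> frozenset[str]:
        return frozenset(n for n in self.graph.nodes if n in self.seeds)


@dataclass(frozen=True)
class NetworkComparison:
    """Set algebra over the non-seed genes of two strata's networks."""

    label_a: str
    label_b: str
    common_genes: frozenset[str]
    exclusive_to_a: frozenset[str]
    exclusive_to_b: frozenset[str]


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among rows (average ranks for ties)."""
    ranks = rankdata(values.to_numpy(), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


def compute_seed_correlations(study: CohortStudy, seeds: list[str]) -> list[CandidateEdge]:
    """Spearman correlation of every non-seed gene with every seed gene.

    Seeds absent from the study are logged and skipped.  Non-seed genes with
    zero variance (undefined rank correlation) are skipped with a log entry.
    """
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    present = [s for s in seeds if s in study.expression.values.index]
    absent = sorted(set(seeds) - set(present))
    if absent:
        log.warning("compute_seed_correlations: %d seeds absent: %s", len(absent), absent[:10])
    if not present:
        raise ValueError("no seed genes present in study")
    seed_set = set(seeds)
    partners = [g for g in study.genes if g not in seed_set]

    vals = study.expression.values
    ranks = rankdata(vals.to_numpy(), axis=1)
    sd = ranks.std(axis=1)
    gene_pos = {g: i for i, g in enumerate(study.genes)}
    zero_var = [g for g in partners if sd[gene_pos[g]] == 0]
    if zero_var:
        log.warning("skipping %d zero-variance genes", len(zero_var))
        partners = [g for g in partners if sd[gene_pos[g]] > 0]

    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    seed_idx = [gene_pos[s] for s in present]
    part_idx = [gene_pos[g] for g in partners]
    num = centered[seed_idx] @ centered[part_idx].T
    denom = np.outer(norm[seed_idx], norm[part_idx])
    rho = num / denom

    edges = []
    for i, s in enumerate(present):
        for j, g in enumerate(partners):
            edges.append(CandidateEdge(s, g, float(rho[i, j])))
    return edges


# ---------------------------------------------------------------------------
# Greedy edge selection
# ---------------------------------------------------------------------------

def select_edges(
    candidates: list[CandidateEdge],
    threshold: float = 0.9,
    edge_limit: int = 1,
    absolute: bool = False,
) -> list[CandidateEdge]:
    """Greedy edge selection from the strongest correlation down.

    Only candidates with rho > threshold (|rho| when ``absolute``) are
    considered.  Processing in descending correlation, an edge is kept iff
    its non-seed partner currently holds fewer than ``edge_limit`` kept
    edges; seeds may anchor any number of edges.  Ties are broken by
    (seed symbol, partner symbol) lexicographic order for determinism.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if edge_limit < 1:
        raise ValueError("edge_limit must be >= 1")
    strength = (lambda e: abs(e.rho)) if absolute else (lambda e: e.rho)
    eligible = [e for e in candidates if strength(e) > threshold]
    eligible.sort(key=lambda e: (-strength(e), e.seed_gene, e.partner_gene))
    degree: dict[str, int] = {}
    kept = []
    for e in eligible:
        if degree.get(e.partner_gene, 0) < edge_limit:
            kept.append(e)
            degree[e.partner_gene] = degree.get(e.partner_gene, 0) + 1
    return kept


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_genes(
    genes: list[str],
    study: CohortStudy,
    cut_mode: str = "max",
) -> dict[str, int]:
    """Complete-linkage clusters of network genes on distance 1 - Spearman.

    The dendrogram is cut at (maximum merge height)/1.5 by default
    (``cut_mode="max"``); ``cut_mode="total"`` instead cuts at (sum of merge
    heights)/1.5, an alternative reading of the same rule.  Cluster IDs are
    1-based, ordered by each cluster's alphabetically first gene.
    """
    if not genes:
        raise ValueError("cluster_genes requires at least one gene")
    if cut_mode not in ("max", "total"):
        raise ValueError(f"unknown cut_mode {cut_mode!r}")
    if len(genes) == 1:
        return {genes[0]: 1}
    corr = spearman_matrix(study.expression.values.loc[list(genes)])
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="complete")
    heights = Z[:, 2]
    cut = (heights.max() if cut_mode == "max" else heights.sum()) / 1.5
    labels = fcluster(Z, t=cut, criterion="distance")
    return _relabel_clusters(genes, labels)


def _relabel_clusters(genes: list[str], labels: np.ndarray) -> dict[str, int]:
    """Stable 1-based IDs ordered by each cluster's alphabetically first gene."""
    members: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        members.setdefault(int(lab), []).append(g)
    order = sorted(members, key=lambda lab: min(members[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return {g: remap[int(lab)] for g, lab in zip(genes, labels)}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _frame_color(p: float) -> str:
    if np.isfinite(p) and p < 0.01:
        return "yellow"
    if np.isfinite(p) and p < 0.05:
        return "red"
    return "none"


def annotate_nodes(
    network: GeneNetwork,
    stratum_study: CohortStudy,
    full_study: CohortStudy,
    cox: dict[str, CoxResult],
    cut_mode: str = "max",
) -> GeneNetwork:
    """Attach cv, cluster, shape, frame and direction attributes to all nodes.

    cv (= sd/mean, absolute value) and clusters come from the stratum's
    samples; Cox p-values (frames, stars) and the up/down direction (mean
    expression in recurrent vs non-recurrent cases) come from the full
    cohort.
    """
    g = network.graph
    nodes = sorted(g.nodes)
    missing_cox = [n for n in nodes if n not in network.seeds and n not in cox]
    if missing_cox:
        raise ValueError(f"Cox results missing for non-seed genes: {missing_cox[:5]}")
    clusters = cluster_genes(nodes, stratum_study, cut_mode=cut_mode) if nodes else {}

    event = full_study.clinical["recurrence_event"].astype(float)
    ev_mask = (event == 1).to_numpy()
    nev_mask = (event == 0).to_numpy()

    for n in nodes:
        x_strat = stratum_study.gene_values(n).to_numpy()
        mean = x_strat.mean()
        if mean == 0:
            raise ValueError(f"gene {n!r} has zero mean expression; cv undefined")
        cv = abs(x_strat.std(ddof=1) / mean)

        x_full = full_study.gene_values(n).to_numpy()
        direction = "up" if x_full[ev_mask].mean() > x_full[nev_mask].mean() else "down"

        is_seed = n in network.seeds
        p = cox[n].p if n in cox else np.nan
        if is_seed:
            shape = "diamond"
        elif np.isfinite(p) and p < 0.05:
            shape = "star"
        else:
            shape = "circle"
        g.nodes[n].update(
            cv=float(cv),
            cluster=int(clusters[n]),
            shape=shape,
            frame=_frame_color(p),
            direction=direction,
            is_seed=bool(is_seed),
        )
    return network


# ---------------------------------------------------------------------------
# Stratified construction and comparison
# ---------------------------------------------------------------------------

def _stratum_masks(study: CohortStudy, variables: list[str]) -> dict[str, pd.Series]:
    """Strata from the cross-product of observed levels of clinical variables."""
    colmap = {"recurrence": "recurrence_event", "node": "node_status"}
    series = []
    for v in variables:
        col = colmap.get(v, v)
        if col not in study.clinical.columns:
            raise KeyError(f"unknown stratification variable {v!r}")
        series.append((v, study.clinical[col].astype(float)))
    strata: dict[str, pd.Series] = {}
    for combo in itertools.product([1.0, 0.0], repeat=len(series)):
        mask = pd.Series(True, index=study.clinical.index)
        parts = []
        for (v, s), level in zip(series, combo):
            mask &= s == level
            parts.append(f"{v}{'+' if level == 1.0 else '-'}")
        label = "/".join(parts)
        if mask.any():
            strata[label] = mask
    return strata


def build_network(
    study: CohortStudy,
    seeds: list[str],
    full_study: CohortStudy,
    cox: dict[str, CoxResult],
    stratum: str = "all",
    threshold: float = 0.9,
    edge_limit: int = 1,
    absolute: bool = False,
    cut_mode: str = "max",
) -> GeneNetwork:
    """Correlate -> select -> cluster -> annotate for one sample subset."""
    candidates = compute_seed_correlations(study, seeds)
    kept = select_edges(candidates, threshold=threshold, edge_limit=edge_limit, absolute=absolute)
    g = nx.Graph()
    for e in sorted(kept, key=lambda e: (e.seed_gene, e.partner_gene)):
        g.add_edge(e.seed_gene, e.partner_gene, weight=float(e.rho))
    net = GeneNetwork(graph=g, stratum=stratum, seeds=frozenset(seeds))
    return annotate_nodes(net, study, full_study, cox, cut_mode=cut_mode)


def build_stratum_networks(
    study: CohortStudy,
    seeds: list[str],
    variables: list[str],
    threshold: float = 0.9,
    edge_limit: int = 1,
    absolute: bool = False,
    cut_mode: str = "max",
    min_samples: int = 20,
    cox_cache: dict[str, CoxResult] | None = None,
) -> dict[str, GeneNetwork]:
    """One annotated network per stratum of the grouping variables.

    Correlation, selection, clustering and cv use only the stratum's samples;
    node-adjusted Cox annotation is computed once on the full study.  Strata
    smaller than ``min_samples`` raise, naming the stratum.
    """
    strata = _stratum_masks(study, variables)
    for label, mask in strata.items():
        if int(mask.sum()) < min_samples:
            raise ValueError(
                f"stratum {label!r} has {int(mask.sum())} samples (< min_samples={min_samples})"
            )
    cox = cox_cache if cox_cache is not None else {}
    networks = {}
    for label, mask in strata.items():
        sub = study.subset_samples(list(study.clinical.index[mask]))
        candidates = compute_seed_correlations(sub, seeds)
        kept = select_edges(candidates, threshold=threshold, edge_limit=edge_limit,
                            absolute=absolute)
        need = sorted({e.partner_gene for e in kept} - cox.keys())
        if need:
            for r in screen_genes(study, need):
                cox[r.term] = r
        g = nx.Graph()
        for e in sorted(kept, key=lambda e: (e.seed_gene, e.partner_gene)):
            g.add_edge(e.seed_gene, e.partner_gene, weight=float(e.rho))
        net = GeneNetwork(graph=g, stratum=label, seeds=frozenset(seeds))
        networks[label] = annotate_nodes(net, sub, study, cox, cut_mode=cut_mode)
    return networks


def compare_networks(a: GeneNetwork, b: GeneNetwork) -> NetworkComparison:
    """Common and exclusive non-seed genes of two strata's networks."""
    na, nb = a.nonseed_nodes, b.nonseed_nodes
    return NetworkComparison(
        label_a=a.stratum,
        label_b=b.stratum,
        common_genes=na & nb,
        exclusive_to_a=na - nb,
        exclusive_to_b=nb - na,
    )
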