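"""Network construction: correlation, greedy selection, clustering, annotation."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from gcna import (
    CandidateEdge,
    build_stratum_networks,
    cluster_genes,
    compare_networks,
    compute_seed_correlations,
    select_edges,
    spearman_matrix,
)
from gcna.network import GeneNetwork, annotate_nodes
from gcna.survival import CoxResult

import networkx as nx

from conftest import make_study


def _cox(term, p, b=-0.1):
    return CoxResult(term=term, B=b, HR=float(np.exp(b)), p=p,
                     ci_low=0.5, ci_high=1.5, covariates=["node"])


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def test_seed_correlations_recover_monotone_relations():
    rng = np.random.default_rng(0)
    seed = rng.normal(7, 1, 40)
    vals = np.vstack([seed, np.exp(seed / 4), -seed, rng.normal(7, 1, 40)])
    study = make_study(vals, ["SEED", "MONO", "ANTI", "NOISE"])
    edges = {(e.seed_gene, e.partner_gene): e.rho
             for e in compute_seed_correlations(study, ["SEED"])}
    assert edges[("SEED", "MONO")] == pytest.approx(1.0)
    assert edges[("SEED", "ANTI")] == pytest.approx(-1.0)
    assert abs(edges[("SEED", "NOISE")]) < 0.5


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(6, 25))  # untied with probability 1
    study = make_study(7 + vals, [f"g{i}" for i in range(6)])
    edges = compute_seed_correlations(study, ["g0"])
    for e in edges:
        a = rankdata(study.gene_values("g0").to_numpy())
        b = rankdata(study.gene_values(e.partner_gene).to_numpy())
        oracle = np.corrcoef(a, b)[0, 1]
        assert e.rho == pytest.approx(oracle, abs=1e-12)


def test_seed_correlations_require_three_samples():
    study = make_study(np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"],
                       event=np.array([0.0, 1.0]), time=np.array([1.0, 2.0]),
                       node=np.array([0.0, 1.0]))
    with pytest.raises(ValueError, match="3 samples"):
        compute_seed_correlations(study, ["a"])


# ---------------------------------------------------------------------------
# Greedy selection
# ---------------------------------------------------------------------------

def test_partner_keeps_single_strongest_edge():
    cands = [CandidateEdge("A", "X", 0.95), CandidateEdge("B", "X", 0.92)]
    kept = select_edges(cands, threshold=0.9, edge_limit=1)
    assert [(e.seed_gene, e.partner_gene) for e in kept] == [("A", "X")]


def test_threshold_excludes_weak_candidates():
    cands = [CandidateEdge("A", "X", 0.9), CandidateEdge("A", "Y", 0.3)]
    assert select_edges(cands, threshold=0.9) == []


def test_ties_break_lexicographically():
    cands = [CandidateEdge("B", "X", 0.95), CandidateEdge("A", "X", 0.95)]
    kept = select_edges(cands)
    assert [(e.seed_gene, e.partner_gene) for e in kept] == [("A", "X")]


def test_absolute_mode_admits_negative_correlations():
    cands = [CandidateEdge("A", "X", -0.95)]
    assert select_edges(cands) == []
    assert len(select_edges(cands, absolute=True)) == 1


def brute_force_select(cands, threshold=0.9, edge_limit=1):
    """Literal replay: repeatedly take the globally strongest remaining
    candidate above threshold whose partner is not yet saturated."""
    remaining = [e for e in cands if e.rho > threshold]
    kept, degree = [], {}
    while remaining:
        best = min(remaining, key=lambda e: (-e.rho, e.seed_gene, e.partner_gene))
        remaining.remove(best)
        if degree.get(best.partner_gene, 0) < edge_limit:
            kept.append(best)
            degree[best.partner_gene] = degree.get(best.partner_gene, 0) + 1
    return kept


def test_selection_equals_bruteforce_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(50):
        seeds = [f"S{i}" for i in range(4)]
        partners = [f"P{i}" for i in range(20)]
        limit = int(rng.integers(1, 4))
        cands = [
            CandidateEdge(s, p, round(float(rng.uniform(0.8, 1.0)), 2))  # rounding forces ties
            for s in seeds for p in partners
        ]
        kept = select_edges(cands, threshold=0.9, edge_limit=limit)
        oracle = brute_force_select(cands, threshold=0.9, edge_limit=limit)
        assert kept == oracle
        degrees = {}
        for e in kept:
            assert e.rho > 0.9
            degrees[e.partner_gene] = degrees.get(e.partner_gene, 0) + 1
        assert all(d <= limit for d in degrees.values())


def test_raising_threshold_never_adds_edges():
    rng = np.random.default_rng(7)
    cands = [CandidateEdge(f"S{i%3}", f"P{j}", float(rng.uniform(0.8, 1.0)))
             for i in range(3) for j in range(15)]
    lo = {(e.seed_gene, e.partner_gene) for e in select_edges(cands, threshold=0.9)}
    hi = {(e.seed_gene, e.partner_gene) for e in select_edges(cands, threshold=0.95)}
    assert hi <= lo


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_two_separated_blocks_give_two_clusters():
    rng = np.random.default_rng(2)
    base1, base2 = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
    vals = 7 + np.vstack([base1, base1 * 2 + 1, base2, base2 * 3 - 1])
    study = make_study(vals, ["a1", "a2", "b1", "b2"])
    clusters = cluster_genes(["a1", "a2", "b1", "b2"], study)
    assert clusters["a1"] == clusters["a2"]
    assert clusters["b1"] == clusters["b2"]
    assert clusters["a1"] != clusters["b1"]
    assert len(set(clusters.values())) == 2


def test_single_gene_single_cluster():
    study = make_study(np.random.default_rng(3).normal(7, 1, (1, 10)), ["only"])
    assert cluster_genes(["only"], study) == {"only": 1}


def brute_force_complete_linkage(dist, cut):
    """Naive agglomerative complete linkage: merge closest pair until the
    next merge height exceeds the cut."""
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    while len(clusters) > 1:
        best, pair = np.inf, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
            if d < best - 1e-15:
                best, pair = d, (i, j)
        if best > cut:
            break
        i, j = pair
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


def test_clustering_matches_bruteforce_oracle_on_small_instances():
    rng = np.random.default_rng(4)
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    for trial in range(20):
        k = int(rng.integers(3, 8))
        genes = [f"g{i}" for i in range(k)]
        study = make_study(7 + rng.normal(0, 1, (k, 30)), genes)
        got = cluster_genes(genes, study)

        corr = spearman_matrix(study.expression.values.loc[genes]).to_numpy()
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform((dist + dist.T) / 2, checks=False), method="complete")
        cut = Z[:, 2].max() / 1.5
        oracle = brute_force_complete_linkage((dist + dist.T) / 2, cut)
        oracle_sets = {frozenset(genes[i] for i in c) for c in oracle}
        got_sets = {frozenset(g for g, lab in got.items() if lab == v)
                    for v in set(got.values())}
        assert got_sets == oracle_sets


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _toy_network():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 1, 60)
    vals = 7 + np.vstack([base, base + rng.normal(0, 0.1, 60),
                          base + rng.normal(0, 0.1, 60), rng.normal(0, 1, 60)])
    event = (rng.random(60) < 0.4).astype(float)
    study = make_study(vals, ["SEED1", "X", "Y", "Z"], event=event)
    g = nx.Graph()
    g.add_edge("SEED1", "X", weight=0.99)
    g.add_edge("SEED1", "Y", weight=0.98)
    g.add_edge("SEED1", "Z", weight=0.97)
    net = GeneNetwork(graph=g, stratum="all", seeds=frozenset({"SEED1"}))
    return net, study


@pytest.mark.parametrize("p, frame, shape", [
    (0.03, "red", "star"),     # 0.01 <= p < 0.05
    (0.005, "yellow", "star"),  # p < 0.01
    (0.2, "none", "circle"),    # not significant
])
def test_frame_and_shape_follow_p_value_rules(p, frame, shape):
    net, study = _toy_network()
    cox = {"X": _cox("X", p), "Y": _cox("Y", 0.5), "Z": _cox("Z", 0.5)}
    out = annotate_nodes(net, study, study, cox)
    assert out.graph.nodes["X"]["frame"] == frame
    assert out.graph.nodes["X"]["shape"] == shape
    assert out.graph.nodes["SEED1"]["shape"] == "diamond"


def test_annotation_attaches_cv_cluster_direction():
    net, study = _toy_network()
    cox = {n: _cox(n, 0.5) for n in ["X", "Y", "Z"]}
    out = annotate_nodes(net, study, study, cox)
    for n in out.graph.nodes:
        attrs = out.graph.nodes[n]
        x = study.gene_values(n).to_numpy()
        assert attrs["cv"] == pytest.approx(abs(x.std(ddof=1) / x.mean()))
        assert attrs["direction"] in ("up", "down")
        assert attrs["cluster"] >= 1
    # SEED1, X, Y co-vary; Z is independent noise
    assert out.graph.nodes["SEED1"]["cluster"] == out.graph.nodes["X"]["cluster"]
    assert out.graph.nodes["Z"]["cluster"] != out.graph.nodes["X"]["cluster"]


def test_annotation_requires_cox_for_nonseed_genes():
    net, study = _toy_network()
    with pytest.raises(ValueError, match="Cox results missing"):
        annotate_nodes(net, study, study, {"X": _cox("X", 0.5)})


# ---------------------------------------------------------------------------
# Stratified construction and comparison
# ---------------------------------------------------------------------------

def test_stratified_networks_one_per_group(block_study):
    seeds = ["LST1", "IGHM", "CAND01", "CAND02"]
    nets = build_stratum_networks(block_study, seeds, ["recurrence"])
    assert set(nets) == {"recurrence+", "recurrence-"}
    nets4 = build_stratum_networks(block_study, seeds, ["node", "recurrence"])
    assert set(nets4) == {"node+/recurrence+", "node+/recurrence-",
                          "node-/recurrence+", "node-/recurrence-"}
    for net in nets.values():
        for _, _, w in net.graph.edges(data="weight"):
            assert w > 0.9
        for n in net.nonseed_nodes:
            assert net.graph.degree[n] <= 1


def test_small_stratum_raises_with_name(block_study):
    with pytest.raises(ValueError, match="recurrence"):
        build_stratum_networks(block_study, ["LST1", "IGHM"], ["recurrence"],
                               min_samples=10**6)


def test_compare_identity_and_disjoint():
    g1 = nx.Graph()
    g1.add_edge("S", "X", weight=0.95)
    g1.add_edge("S", "Y", weight=0.95)
    a = GeneNetwork(graph=g1, stratum="a", seeds=frozenset({"S"}))
    same = GeneNetwork(graph=g1.copy(), stratum="b", seeds=frozenset({"S"}))
    cmp_ = compare_networks(a, same)
    assert cmp_.common_genes == {"X", "Y"}
    assert cmp_.exclusive_to_a == cmp_.exclusive_to_b == frozenset()

    g2 = nx.Graph()
    g2.add_edge("S", "Z", weight=0.95)
    b = GeneNetwork(graph=g2, stratum="b", seeds=frozenset({"S"}))
    cmp2 = compare_networks(a, b)
    assert cmp2.common_genes == frozenset()
    # disjoint and exhaustive over all non-seed nodes
    union = cmp2.common_genes | cmp2.exclusive_to_a | cmp2.exclusive_to_b
    assert union == a.nonseed_nodes | b.nonseed_nodes
    assert not (cmp2.exclusive_to_a & cmp2.exclusive_to_b)
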