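"""TO-GCN construction: correlation edges, BFS levels, stage maps."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import petalnet as pn
from petalnet.network import assign_levels, build_edges


def edges_df(pairs):
    """(u, v, kind_u, kind_v, pcc) rows from simple tuples."""
    return pd.DataFrame(pairs, columns=["node_u", "node_v", "kind_u", "kind_v", "pcc"])


# -- pcc ----------------------------------------------------------------------

def test_pcc_basic_values():
    assert pn.pcc([1, 2, 3, 5], [1, 2, 3, 5]) == pytest.approx(1.0)
    assert pn.pcc([1, 2, 3, 5], [-1, -2, -3, -5]) == pytest.approx(-1.0)
    assert pn.pcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_pcc_errors():
    with pytest.raises(ValueError):
        pn.pcc([1, 2], [3, 4])  # too short
    with pytest.raises(ValueError):
        pn.pcc([1, 1, 1, 1], [1, 2, 3, 4])  # constant


# -- build_edges --------------------------------------------------------------

def test_edge_cutoffs_are_boundary_inclusive(samples12):
    """PCC exactly at the cutoff forms an edge; just below does not."""
    rng = np.random.default_rng(0)
    base = rng.normal(size=12)

    def with_corr(x, rho):
        # construct y with exact sample correlation rho to x
        z = rng.normal(size=12)
        xc = (x - x.mean()) / x.std()
        zc = z - z.mean()
        zc -= xc * (zc @ xc) / (xc @ xc)
        zc /= zc.std()
        return rho * xc + np.sqrt(1 - rho**2) * zc

    rows = np.vstack([base, with_corr(base, 0.90), with_corr(base, 0.89)])
    rows = rows - rows.min() + 1.0
    samples = pn.make_sample_sheet(3)
    expr = pn.ExpressionMatrix(
        pd.DataFrame(rows, index=["g1", "g2", "g3"], columns=[s.sample_id for s in samples]),
        samples,
    )
    catalog = pn.GeneCatalog({"g1": ("tf", "MYB"), "g2": ("tf", "bHLH"), "g3": ("tf", "WRKY")})
    cfg = pn.TOGCNConfig(seed_gene="g1", transform="raw")
    edges = build_edges(expr, None, catalog, ["g1", "g2", "g3"], (), cfg)
    pairs = {frozenset((r.node_u, r.node_v)) for _, r in edges.iterrows()}
    assert frozenset(("g1", "g2")) in pairs
    assert frozenset(("g1", "g3")) not in pairs


def test_noiseless_edges_match_brute_force_oracle(noiseless):
    """All-pairs correlation oracle reproduces build_edges exactly, and the
    gene-gene edge set is precisely the within- and adjacent-level pairs."""
    cfg = pn.TOGCNConfig(seed_gene=noiseless.truth.seed_gene)
    genes = noiseless.expression.gene_ids
    mets = sorted(noiseless.truth.differential_metabolites)
    edges = build_edges(
        noiseless.expression, noiseless.metabolites, noiseless.catalog, genes, mets, cfg
    )
    got = {frozenset((r.node_u, r.node_v)) for _, r in edges.iterrows()}

    # brute-force oracle over the same transform
    data = {g: np.log10(noiseless.expression.values.loc[g].to_numpy() + 1) for g in genes}
    data.update(
        {m: np.log10(noiseless.metabolites.values.loc[m].to_numpy() + 1) for m in mets}
    )
    expected = set()
    for a, b in itertools.combinations(list(genes) + list(mets), 2):
        both_gene = not (a.startswith("M") or b.startswith("M"))
        both_met = a.startswith("M") and b.startswith("M")
        if both_met:
            continue
        r = np.corrcoef(data[a], data[b])[0, 1]
        if r >= (cfg.cutoff_gene if both_gene else cfg.cutoff_metabolite):
            expected.add(frozenset((a, b)))
    assert got == expected

    # gene-gene edges are exactly the within-level and adjacent-level pairs
    lv = noiseless.truth.planted_level
    gene_pairs = {e for e in got if all(not n.startswith("M") for n in e)}
    planted_adjacent = {
        frozenset((a, b))
        for a, b in itertools.combinations(genes, 2)
        if abs(lv[a] - lv[b]) <= 1
    }
    assert gene_pairs == planted_adjacent


def test_empty_differential_set_is_an_error(noiseless):
    cfg = pn.TOGCNConfig(seed_gene=noiseless.truth.seed_gene)
    with pytest.raises(ValueError):
        build_edges(noiseless.expression, None, noiseless.catalog, [], (), cfg)


def test_raising_cutoff_never_adds_edges(study):
    genes = study.expression.gene_ids
    counts = []
    for cutoff in (0.85, 0.90, 0.95):
        cfg = pn.TOGCNConfig(seed_gene=study.truth.seed_gene, cutoff_gene=cutoff)
        counts.append(len(build_edges(study.expression, None, study.catalog, genes, (), cfg)))
    assert counts[0] >= counts[1] >= counts[2]


# -- assign_levels ------------------------------------------------------------

def test_seed_alone_is_level_one():
    cfg = pn.TOGCNConfig(seed_gene="s")
    togcn = assign_levels(edges_df([]), cfg)
    assert togcn.level("s") == 1
    assert togcn.levels() == {"s": 1}


def test_path_levels():
    cfg = pn.TOGCNConfig(seed_gene="s")
    togcn = assign_levels(
        edges_df([("s", "a", "tf", "tf", 0.95), ("a", "b", "tf", "tf", 0.95)]), cfg
    )
    assert [togcn.level(n) for n in ("s", "a", "b")] == [1, 2, 3]


def test_min_neighbor_rule():
    """A node adjacent to both an L1 and an L2 node is assigned L2."""
    cfg = pn.TOGCNConfig(seed_gene="s")
    togcn = assign_levels(
        edges_df(
            [
                ("s", "a", "tf", "tf", 0.95),
                ("s", "x", "tf", "tf", 0.95),
                ("a", "x", "tf", "tf", 0.95),
            ]
        ),
        cfg,
    )
    assert togcn.level("x") == 2


def test_levels_equal_bfs_distance_on_random_graphs():
    """Level assignment == shortest-path distance + 1 (networkx oracle)."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        n = int(rng.integers(5, 50))
        p = rng.uniform(0.05, 0.3)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        g.add_edge(0, 1)  # the seed must appear in the edge set
        rows = [
            (f"n{u}", f"n{v}", "tf", "tf", 0.95) for u, v in g.edges
        ]
        cfg = pn.TOGCNConfig(seed_gene="n0")
        togcn = assign_levels(edges_df(rows), cfg)
        dist = nx.single_source_shortest_path_length(g, 0)
        for u in g.nodes:
            if not togcn.graph.has_node(f"n{u}"):
                assert g.degree(u) == 0  # isolated nodes never enter the network
                continue
            expected = dist[u] + 1 if u in dist else None
            assert togcn.level(f"n{u}") == expected


def test_unreachable_nodes_are_reported():
    cfg = pn.TOGCNConfig(seed_gene="s")
    togcn = assign_levels(
        edges_df([("s", "a", "tf", "tf", 0.95), ("x", "y", "tf", "tf", 0.95)]), cfg
    )
    assert togcn.unassigned == {"x", "y"}


def test_metabolites_inherit_best_neighbor_level_and_never_propagate():
    cfg = pn.TOGCNConfig(seed_gene="s")
    togcn = assign_levels(
        edges_df(
            [
                ("s", "a", "tf", "structural_gene", 0.95),
                ("m", "s", "metabolite", "tf", 0.80),
                ("m", "a", "metabolite", "structural_gene", 0.92),
                ("m", "b", "metabolite", "tf", 0.99),  # b unreachable gene
            ]
        ),
        cfg,
    )
    # b is unassigned, so the metabolite takes its best *assigned* neighbor (a)
    assert togcn.level("m") == togcn.level("a") == 2
    assert "b" in togcn.unassigned
    # the metabolite did not give b a level
    assert togcn.level("b") is None


def test_missing_seed_is_an_error():
    cfg = pn.TOGCNConfig(seed_gene="missing")
    with pytest.raises(ValueError):
        assign_levels(edges_df([("a", "b", "tf", "tf", 0.95)]), cfg)


# -- peak stages and summaries ------------------------------------------------

@pytest.mark.parametrize(
    "means,expected",
    [
        ({"T1": 5, "T2": 1, "T3": 1, "T4": 1}, "T1"),
        ({"T1": 1, "T2": 1, "T3": 1, "T4": 5}, "T4"),
        ({"T1": 3, "T2": 3, "T3": 1, "T4": 1}, "T1"),  # tie -> earlier
    ],
)
def test_node_peak_stage(means, expected):
    assert pn.node_peak_stage(means) == expected


def test_level_stage_map_two_levels_per_stage(noiseless, noiseless_pipeline):
    """The planted 8-level cascade maps L1-2->T1, L3-4->T2, L5-6->T3, L7-8->T4."""
    mapping = pn.level_stage_map(noiseless_pipeline.togcn, noiseless.expression)
    assert mapping == {1: "T1", 2: "T1", 3: "T2", 4: "T2", 5: "T3", 6: "T3", 7: "T4", 8: "T4"}


def test_level_stage_map_majority_and_monotone_repair(samples12):
    # two levels; the second level's majority peak is earlier -> repaired
    profiles = {
        "s": [9, 5, 1, 1],
        "a": [1, 9, 5, 1],  # L2 majority: T2
        "b": [1, 9, 4, 1],
        "c": [9, 2, 1, 1],  # minority voter peaking T1
    }
    rows = np.array([np.repeat(profiles[g], 3) for g in profiles], dtype=float)
    # columns must follow sample order T1..T4 x reps; build accordingly
    arranged = np.array(
        [np.array([[p[0]] * 3 + [p[1]] * 3 + [p[2]] * 3 + [p[3]] * 3 for p in [profiles[g]]])[0] for g in profiles]
    )
    expr = pn.ExpressionMatrix(
        pd.DataFrame(arranged, index=list(profiles), columns=[s.sample_id for s in samples12]),
        samples12,
    )
    cfg = pn.TOGCNConfig(seed_gene="s")
    togcn = assign_levels(
        edges_df(
            [
                ("s", "a", "tf", "tf", 0.95),
                ("s", "b", "tf", "tf", 0.95),
                ("s", "c", "tf", "tf", 0.95),
            ]
        ),
        cfg,
    )
    mapping = pn.level_stage_map(togcn, expr)
    assert mapping[2] == "T2"  # 2-of-3 majority; minority T1 voter ignored
    assert pn.STAGES.index(mapping[2]) >= pn.STAGES.index(mapping[1])


def test_network_summary_conserves_counts(study, study_pipeline):
    togcn = study_pipeline.togcn
    summary = pn.network_summary(togcn, study.expression)
    assert summary["nodes"]["count"].sum() == togcn.graph.number_of_nodes()
    assert summary["edges"]["count"].sum() == togcn.graph.number_of_edges()


def test_study_network_recovers_planted_structure(study, study_pipeline):
    """On the reference study (noise 0.1), >= 90% of planted levels are
    recovered and edge weights always meet their cutoff."""
    togcn = study_pipeline.togcn
    assert pn.level_recovery(togcn, study.truth) >= 0.9
    for u, v, d in togcn.graph.edges(data=True):
        both_gene = togcn.kind(u) != "metabolite" and togcn.kind(v) != "metabolite"
        cutoff = togcn.config.cutoff_gene if both_gene else togcn.config.cutoff_metabolite
        assert d["pcc"] >= cutoff
        assert u != v
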