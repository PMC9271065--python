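"""Time-ordered gene co-expression network (TO-GCN) construction.

Edges connect differential features whose Pearson correlation over the
replicate samples reaches a type-dependent cutoff: 0.90 for gene-gene
pairs, 0.73 for metabolite-gene pairs (metabolite-metabolite pairs carry
no edges).  Anchored at a seed transcription factor known to act first,
genes are stratified into time-ordered levels L1, L2, ... by breadth-first
propagation: the seed is L1 and every other reachable gene sits one level
after its earliest-level gene neighbour.  Metabolites are terminal
annotations: they inherit the level of their best-correlated gene
neighbour and never propagate levels themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .core import STAGES, ExpressionMatrix, GeneCatalog, MetaboliteMatrix
from .screening import stage_means


@dataclass
class TOGCNConfig:
    """Seed gene and correlation cutoffs of the network.

    ``use_stage_means`` switches the correlation substrate from the
    replicate-level samples (default; more degrees of freedom) to the four
    stage means.  ``transform`` selects the scale on which correlations
    are computed: ``"log10p1"`` (log10(x+1), the package's standard
    expression transform; multiplicative replicate noise is homoscedastic
    on this scale) or ``"raw"``.
    """

    seed_gene: str
    cutoff_gene: float = 0.90
    cutoff_metabolite: float = 0.73
    max_levels: int | None = None
    use_stage_means: bool = False
    transform: str = "log10p1"

    def __post_init__(self) -> None:
        for name in ("cutoff_gene", "cutoff_metabolite"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.transform not in ("log10p1", "raw"):
            raise ValueError("transform must be 'log10p1' or 'raw'")


def pcc(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("vectors must share one dimension")
    if xa.size < 3:
        raise ValueError("need length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(xa, ya)[0, 1])


def build_edges(
    expr: ExpressionMatrix,
    metab: MetaboliteMatrix | None,
    catalog: GeneCatalog,
    differential_genes: Iterable[str],
    differential_metabolites: Iterable[str] = (),
    cfg: TOGCNConfig | None = None,
) -> pd.DataFrame:
    """Correlation edges among differential features under the dual cutoffs.

    Returns a DataFrame (node_u, node_v, kind_u, kind_v, pcc) with one row
    per unordered pair meeting its cutoff (boundary inclusive).  Constant
    features, whose correlation is undefined, are dropped with a warning.
    """
    if cfg is None:
        raise ValueError("a TOGCNConfig with a seed gene is required")
    genes = [g for g in expr.gene_ids if g in set(differential_genes)]
    mets = (
        [m for m in metab.metabolite_ids if m in set(differential_metabolites)]
        if metab is not None
        else []
    )
    if not genes:
        raise ValueError("empty differential gene set")

    def rows(matrix, ids):
        if cfg.use_stage_means:
            vals = stage_means(matrix).loc[ids].to_numpy()
        else:
            vals = matrix.values.loc[ids].to_numpy()
        if cfg.transform == "log10p1":
            vals = np.log10(vals + 1.0)
        return vals

    gvals = rows(expr, genes)
    mvals = rows(metab, mets) if mets else np.empty((0, gvals.shape[1]))
    data = np.vstack([gvals, mvals])
    ids = genes + mets
    const = np.ptp(data, axis=1) == 0
    if const.any():
        warnings.warn(f"dropping constant features: {[ids[i] for i in np.nonzero(const)[0]]}")
        data = data[~const]
        ids = [i for i, c in zip(ids, const) if not c]
        genes = [g for g in genes if g in set(ids)]
        mets = [m for m in mets if m in set(ids)]
    corr = np.corrcoef(data)
    n_genes = len(genes)
    kinds = [catalog.node_kind(g) for g in genes] + ["metabolite"] * len(mets)
    recs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both_gene = i < n_genes and j < n_genes
            both_met = i >= n_genes and j >= n_genes
            if both_met:
                continue
            cutoff = cfg.cutoff_gene if both_gene else cfg.cutoff_metabolite
            if corr[i, j] >= cutoff:
                recs.append((ids[i], ids[j], kinds[i], kinds[j], corr[i, j]))
    return pd.DataFrame(recs, columns=["node_u", "node_v", "kind_u", "kind_v", "pcc"])


@dataclass
class TOGCN:
    """The assembled network: a graph with node kinds and level labels."""

    graph: nx.Graph
    config: TOGCNConfig
    unassigned: set[str] = field(default_factory=set)

    def level(self, node: str) -> int | None:
        return self.graph.nodes[node].get("level")

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def levels(self) -> dict[str, int]:
        return {
            n: d["level"] for n, d in self.graph.nodes(data=True) if d.get("level") is not None
        }

    def nodes_at_level(self, level: int, kind: str | None = None) -> list[str]:
        return [
            n
            for n, d in self.graph.nodes(data=True)
            if d.get("level") == level and (kind is None or d["kind"] == kind)
        ]

    @property
    def n_levels(self) -> int:
        lv = [l for l in self.levels().values()]
        return max(lv) if lv else 0


def assign_levels(edges: pd.DataFrame, cfg: TOGCNConfig) -> TOGCN:
    """Seed-anchored breadth-first level assignment.

    The seed gene is level 1; every gene reachable through gene-gene edges
    gets level = 1 + (shortest-path distance from the seed on the gene-gene
    subgraph).  Genes not reached stay unassigned and are reported.  Each
    metabolite inherits the level of its highest-PCC gene neighbour.
    """
    g = nx.Graph()
    for _, r in edges.iterrows():
        g.add_node(r.node_u, kind=r.kind_u)
        g.add_node(r.node_v, kind=r.kind_v)
        g.add_edge(r.node_u, r.node_v, pcc=float(r.pcc))
    if cfg.seed_gene not in g:
        if g.number_of_nodes() > 0:
            raise ValueError(f"seed gene {cfg.seed_gene!r} absent from the edge set")
        # degenerate singleton network: just the seed, no edges
        g.add_node(cfg.seed_gene, kind="tf")
    gene_nodes = [n for n, d in g.nodes(data=True) if d["kind"] != "metabolite"]
    if cfg.seed_gene not in gene_nodes:
        raise ValueError(f"seed gene {cfg.seed_gene!r} is not a gene node")
    sub = g.subgraph(gene_nodes)
    dist = nx.single_source_shortest_path_length(sub, cfg.seed_gene)
    unassigned: set[str] = set()
    for n in g.nodes:
        g.nodes[n]["level"] = None
    for n, d in dist.items():
        lvl = d + 1
        if cfg.max_levels is not None and lvl > cfg.max_levels:
            continue
        g.nodes[n]["level"] = lvl
    for n in gene_nodes:
        if g.nodes[n]["level"] is None:
            unassigned.add(n)
    for n, d in g.nodes(data=True):
        if d["kind"] != "metabolite":
            continue
        best, best_pcc = None, -np.inf
        for nb in g.neighbors(n):
            if g.nodes[nb]["kind"] == "metabolite":
                continue
            w = g.edges[n, nb]["pcc"]
            if w > best_pcc and g.nodes[nb]["level"] is not None:
                best, best_pcc = nb, w
        if best is None:
            unassigned.add(n)
        else:
            g.nodes[n]["level"] = g.nodes[best]["level"]
    return TOGCN(graph=g, config=cfg, unassigned=unassigned)


def node_peak_stage(stage_mean_row: Mapping[str, float] | pd.Series) -> str:
    """Stage of maximal mean expression; ties break toward the earlier stage."""
    row = pd.Series(stage_mean_row)
    stages = [s for s in STAGES if s in row.index]
    vals = row[stages].to_numpy(dtype=float)
    return stages[int(np.argmax(vals))]


def level_stage_map(togcn: TOGCN, expr: ExpressionMatrix) -> dict[int, str]:
    """Majority peak stage of the gene nodes of each level, monotone-repaired.

    If a later level would map to an earlier stage than its predecessor, it
    inherits the predecessor's stage (levels are time ordered by
    construction, so the map must be non-decreasing).
    """
    sm = stage_means(expr)
    out: dict[int, str] = {}
    for lvl in range(1, togcn.n_levels + 1):
        genes = [
            n
            for n in togcn.nodes_at_level(lvl)
            if togcn.kind(n) != "metabolite" and n in sm.index
        ]
        if not genes:
            warnings.warn(f"level {lvl} has no gene nodes; skipped")
            continue
        peaks = pd.Series([node_peak_stage(sm.loc[g]) for g in genes])
        counts = peaks.value_counts()
        top = counts[counts == counts.max()].index
        out[lvl] = min(top, key=STAGES.index)
    prev = None
    for lvl in sorted(out):
        if prev is not None and STAGES.index(out[lvl]) < STAGES.index(prev):
            out[lvl] = prev
        prev = out[lvl]
    return out


def network_summary(togcn: TOGCN, expr: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """Node counts by (level, stage, kind) and edge counts by kind pair."""
    stage_of_level = level_stage_map(togcn, expr) if togcn.n_levels else {}
    recs = []
    for n, d in togcn.graph.nodes(data=True):
        lvl = d.get("level")
        recs.append(
            {
                "node": n,
                "kind": d["kind"],
                "level": lvl,
                "stage": stage_of_level.get(lvl, "unassigned"),
            }
        )
    nodes = pd.DataFrame(recs)
    if nodes.empty:
        node_counts = pd.DataFrame(columns=["level", "stage", "kind", "count"])
    else:
        node_counts = (
            nodes.groupby(["level", "stage", "kind"], dropna=False)
            .size()
            .reset_index(name="count")
        )
    erecs = []
    for u, v in togcn.graph.edges:
        ku, kv = sorted((togcn.kind(u), togcn.kind(v)))
        erecs.append({"kind_pair": f"{ku}--{kv}"})
    edge_counts = (
        pd.DataFrame(erecs).groupby("kind_pair").size().reset_index(name="count")
        if erecs
        else pd.DataFrame(columns=["kind_pair", "count"])
    )
    return {"nodes": node_counts, "edges": edge_counts, "node_table": nodes}
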