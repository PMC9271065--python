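"""End-to-end pipeline runner and recovery metrics against planted truth.

``run_pipeline`` chains the screens and the network construction exactly
as the analysis is meant to be used: differential genes and metabolites
are selected first, then correlation edges are formed under the dual
cutoffs, then levels are assigned from the seed TF.  The recovery
functions compare the result with a :class:`~petalnet.simulate.SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import TOGCN, TOGCNConfig, assign_levels, build_edges
from .screening import ScreenConfig, de_genes, de_metabolites
from .simulate import SyntheticDataset, SyntheticTruth
from .subnetwork import direct_regulators


@dataclass
class PipelineResult:
    togcn: TOGCN
    de_gene_table: object
    de_metabolite_table: object
    differential_genes: list[str]
    differential_metabolites: list[str]


def run_pipeline(
    dataset: SyntheticDataset,
    screen_cfg: ScreenConfig | None = None,
    net_cfg: TOGCNConfig | None = None,
) -> PipelineResult:
    """Screen, build edges, assign levels; seeded at the planted seed TF."""
    screen_cfg = screen_cfg or ScreenConfig()
    net_cfg = net_cfg or TOGCNConfig(seed_gene=dataset.truth.seed_gene)
    gtab = de_genes(dataset.expression, screen_cfg)
    mtab = de_metabolites(dataset.metabolites, screen_cfg)
    diff_genes = list(gtab.index[gtab.passes])
    if net_cfg.seed_gene not in diff_genes:
        raise ValueError("the seed gene must itself be differential")
    diff_mets = list(mtab.index[mtab.passes])
    edges = build_edges(
        dataset.expression, dataset.metabolites, dataset.catalog, diff_genes, diff_mets, net_cfg
    )
    togcn = assign_levels(edges, net_cfg)
    return PipelineResult(togcn, gtab, mtab, diff_genes, diff_mets)


def level_recovery(togcn: TOGCN, truth: SyntheticTruth) -> float:
    """Fraction of planted gene levels recovered exactly."""
    planted = {n: l for n, l in truth.planted_level.items() if not n.startswith("M")}
    hits = sum(1 for n, l in planted.items() if togcn.graph.has_node(n) and togcn.level(n) == l)
    return hits / len(planted)


def regulator_recovery(togcn: TOGCN, truth: SyntheticTruth) -> tuple[float, float]:
    """(recall, false-discovery rate) of direct-regulator edges.

    Recovered edges are the direct regulators of every structural gene in
    the network; planted edges are the truth's TF -> structural-gene pairs.
    """
    planted = truth.regulator_edges()
    recovered: set[tuple[str, str]] = set()
    for node, data in togcn.graph.nodes(data=True):
        if data["kind"] != "structural_gene" or data.get("level") is None:
            continue
        for tf, _ in direct_regulators(togcn, node):
            recovered.add((tf, node))
    if not planted:
        raise ValueError("truth has no planted regulator edges")
    recall = len(recovered & planted) / len(planted)
    fdr = len(recovered - planted) / len(recovered) if recovered else 0.0
    return recall, fdr


def motif_confirmation_recovery(
    confirmed: dict[str, dict[str, bool | None]],
    truth: SyntheticTruth,
    catalog,
) -> tuple[float, float]:
    """(recall, false-confirmation rate) of motif-confirmed regulator edges.

    ``confirmed`` maps target gene -> {tf: flag}.  A planted edge counts as
    recovered when its TF is confirmed for its target; a confirmation is
    false when the TF's family has no planted motif in that target's
    promoter.
    """
    planted = truth.regulator_edges()
    planted_fams = {}
    for gene, motif_id, _, _ in truth.planted_motifs:
        planted_fams.setdefault(gene, set()).add(motif_id.split(".")[0])
    n_true = n_conf_true = n_conf = n_false = 0
    for target, flags in confirmed.items():
        for tf, flag in flags.items():
            is_planted = (tf, target) in planted
            if is_planted:
                n_true += 1
            if flag:
                n_conf += 1
                if is_planted:
                    n_conf_true += 1
                elif catalog.tf_family(tf) not in planted_fams.get(target, set()):
                    n_false += 1
    recall = n_conf_true / n_true if n_true else 0.0
    false_rate = n_false / n_conf if n_conf else 0.0
    return recall, false_rate
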