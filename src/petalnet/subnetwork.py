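"""Sub-network extraction around a target: direct regulators, hierarchical
upstream TF chains, metabolite-gene association layers, and motif-based
confirmation of regulator edges.

A "direct regulator" of a structural gene is a TF neighbour at the same or
an earlier level (time ordering forbids later-level regulators).  Upstream
chains extend each direct regulator backwards through TF-TF edges whose
levels decrease by exactly one per link, mirroring the L2 -> L3 -> L4
regulator ladders of time-ordered networks; a relaxed mode accepts any
strictly earlier level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import GeneCatalog
from .motifs import BindingHit
from .network import TOGCN

#: metabolite-gene links above this PCC are flagged high confidence
HIGH_CONFIDENCE_PCC = 0.9


@dataclass
class SubNetwork:
    """The extracted neighbourhood of one target node."""

    target: str
    direct_regulators: set[tuple[str, float]] = field(default_factory=set)
    upstream_chains: list[tuple[tuple[str, ...], tuple[float, ...]]] = field(default_factory=list)
    metabolite_links: set[tuple[str, float, bool]] = field(default_factory=set)
    confirmed: dict[str, bool | None] = field(default_factory=dict)


def direct_regulators(togcn: TOGCN, target: str) -> set[tuple[str, float]]:
    """TF neighbours of a structural gene at the same or an earlier level."""
    if target not in togcn.graph:
        raise KeyError(f"unknown node {target!r}")
    if togcn.kind(target) != "structural_gene":
        raise ValueError(f"{target!r} is not a structural gene")
    tl = togcn.level(target)
    if tl is None:
        raise ValueError(f"{target!r} has no assigned level")
    out = set()
    for nb in togcn.graph.neighbors(target):
        if togcn.kind(nb) != "tf":
            continue
        lvl = togcn.level(nb)
        if lvl is not None and lvl <= tl:
            out.add((nb, float(togcn.graph.edges[target, nb]["pcc"])))
    return out


def upstream_chains(
    togcn: TOGCN,
    target: str,
    depth: int,
    exact_step: bool = True,
    max_chains: int = 1000,
) -> list[tuple[tuple[str, ...], tuple[float, ...]]]:
    """All TF regulator chains of length <= depth upstream of ``target``.

    Each chain is reported farthest-upstream-first, ending at a direct
    regulator; successive TFs sit exactly one level earlier per link
    (``exact_step=False`` relaxes this to any strictly earlier level).
    Chains are ordered lexicographically and capped at ``max_chains``.

    The per-chain PCC tuple holds the weight of each link in chain order;
    its last element is the direct-regulator -> target link.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    chains: list[tuple[tuple[str, ...], tuple[float, ...]]] = []

    def extend(chain: list[str], pccs: list[float]) -> None:
        # chain[0] is the farthest-upstream TF found so far; a chain is
        # reported when it is maximal: at depth, or with no upstream parent
        if len(chains) >= max_chains:
            return
        head = chain[0]
        hl = togcn.level(head)
        ups = []
        if len(chain) < depth:
            for nb in togcn.graph.neighbors(head):
                if togcn.kind(nb) != "tf" or nb in chain:
                    continue
                lvl = togcn.level(nb)
                if lvl is None or hl is None:
                    continue
                if (lvl == hl - 1) if exact_step else (lvl < hl):
                    ups.append(nb)
        if not ups:
            chains.append((tuple(chain), tuple(pccs)))
            return
        for nb in sorted(ups):
            extend([nb] + chain, [float(togcn.graph.edges[nb, head]["pcc"])] + pccs)

    for reg, w in sorted(direct_regulators(togcn, target)):
        extend([reg], [w])
    chains.sort(key=lambda c: c[0])
    return chains[:max_chains]


def metabolite_links(togcn: TOGCN, metabolite: str) -> set[tuple[str, float, bool]]:
    """Gene neighbours of a metabolite with the high-confidence flag.

    All returned links already satisfy the metabolite-gene cutoff (they are
    network edges); links with PCC > 0.9 are flagged high confidence.
    """
    if metabolite not in togcn.graph:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    if togcn.kind(metabolite) != "metabolite":
        raise ValueError(f"{metabolite!r} is not a metabolite")
    out = set()
    for nb in togcn.graph.neighbors(metabolite):
        if togcn.kind(nb) == "metabolite":
            continue
        w = float(togcn.graph.edges[metabolite, nb]["pcc"])
        out.add((nb, w, w > HIGH_CONFIDENCE_PCC))
    return out


def extract_subnetwork(
    togcn: TOGCN,
    target: str,
    depth: int = 3,
    exact_step: bool = True,
) -> SubNetwork:
    """Direct regulators, upstream chains and metabolite links of a target."""
    regs = direct_regulators(togcn, target)
    chains = upstream_chains(togcn, target, depth, exact_step=exact_step)
    links = {
        (nb, float(togcn.graph.edges[target, nb]["pcc"]),
         float(togcn.graph.edges[target, nb]["pcc"]) > HIGH_CONFIDENCE_PCC)
        for nb in togcn.graph.neighbors(target)
        if togcn.kind(nb) == "metabolite"
    }
    return SubNetwork(
        target=target, direct_regulators=regs, upstream_chains=chains, metabolite_links=links
    )


def confirm_with_tfbs(
    sub: SubNetwork,
    hits: Iterable[BindingHit],
    family_motifs: Mapping[str, Sequence[str]],
    catalog: GeneCatalog,
) -> SubNetwork:
    """Flag each direct-regulator edge by promoter motif evidence.

    An edge is confirmed (True) when some motif of the regulator's TF
    family has a hit in the target's promoter; False when the family has
    motifs but none hit; None (unconfirmable) when the family has no motif
    in the map.  Topology is never changed.
    """
    target_hits = {h.motif_id for h in hits if h.gene_id == sub.target}
    confirmed: dict[str, bool | None] = {}
    for tf, _ in sub.direct_regulators:
        family = catalog.tf_family(tf)
        motifs = list(family_motifs.get(family, ())) if family else []
        if not motifs:
            confirmed[tf] = None
        else:
            confirmed[tf] = any(m in target_hits for m in motifs)
    return SubNetwork(
        target=sub.target,
        direct_regulators=set(sub.direct_regulators),
        upstream_chains=list(sub.upstream_chains),
        metabolite_links=set(sub.metabolite_links),
        confirmed=confirmed,
    )
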