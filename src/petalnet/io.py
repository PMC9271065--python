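"""Readers and writers for the package's on-disk formats.

Matrices travel as tab-separated tables (rows = features, columns =
sample ids such as ``T2_R1`` that encode stage and replicate), gene roles
as a two-column table, promoters as FASTA, motifs in JASPAR format (via
Biopython), ground truth and dating reports as YAML, networks as
tab-separated edge/node tables or GraphML, and binding hits as BED6 lines
plus a full table with exact p-values.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionMatrix, GeneCatalog, MetaboliteMatrix, OmicsSample
from .motifs import PWM, BindingHit, GeneFeature, PromoterSet
from .network import TOGCN
from .simulate import SyntheticDataset, SyntheticTruth
from .wgd import WGDDating

_SAMPLE_RE = re.compile(r"^(T[1-4])_R(\d+)$")


def _samples_from_columns(columns: Iterable[str]) -> tuple[OmicsSample, ...]:
    samples = []
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(f"sample id {col!r} does not encode stage/replicate (e.g. T1_R1)")
        samples.append(OmicsSample(col, m.group(1), int(m.group(2))))
    return tuple(samples)


# -- matrices ----------------------------------------------------------------

def write_matrix(matrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, _samples_from_columns(df.columns))


def read_metabolites(path, classes: Mapping[str, str] | None = None) -> MetaboliteMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return MetaboliteMatrix(df, _samples_from_columns(df.columns), classes or {})


# -- gene catalog ------------------------------------------------------------

def write_catalog(catalog: GeneCatalog, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trole\n")
        for gene, (kind, detail) in catalog.role.items():
            role = f"{kind}:{detail}" if detail else kind
            fh.write(f"{gene}\t{role}\n")


def read_catalog(path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t")
    role = {}
    for _, r in df.iterrows():
        kind, _, detail = str(r.role).partition(":")
        role[str(r.gene_id)] = (kind, detail)
    return GeneCatalog(role)


# -- sequences ---------------------------------------------------------------

def write_promoters(promoters: PromoterSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="truncated" if gene in promoters.truncated else "")
        for gene, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_promoters(path) -> PromoterSet:
    sequences, truncated = {}, set()
    for rec in SeqIO.parse(path, "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
        if "truncated" in rec.description:
            truncated.add(rec.id)
    return PromoterSet(sequences, truncated)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_gff3_genes(path) -> list[GeneFeature]:
    """Gene features (1-based inclusive coordinates) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    feats = []
    for f in db.features_of_type("gene"):
        feats.append(GeneFeature(f.id, f.seqid, f.start, f.end, f.strand))
    return feats


# -- motifs ------------------------------------------------------------------

def write_jaspar(pwms: Sequence[PWM], path, n_sites: int = 100) -> None:
    """Write motifs in JASPAR format (probabilities scaled to counts).

    The PWM's stored probabilities include the pseudocount regularization;
    it is inverted here so that reading the file back (which re-applies the
    pseudocount) reproduces the original matrix.
    """
    mots = []
    for p in pwms:
        raw = np.clip(p.probs * (1.0 + 4 * p.pseudocount) - p.pseudocount, 0.0, None)
        raw = raw / raw.sum(axis=0, keepdims=True)
        counts = {b: (raw[i] * n_sites).tolist() for i, b in enumerate("ACGT")}
        m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = p.motif_id
        m.name = p.tf_family
        mots.append(m)
    with open(path, "w") as fh:
        fh.write(bio_motifs.write(mots, "jaspar"))


def read_jaspar(path, background=None, pseudocount: float = 0.01) -> list[PWM]:
    with open(path) as fh:
        mots = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in mots:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        pwms.append(
            PWM(
                motif_id=m.matrix_id or m.name,
                tf_family=m.name or "",
                probs=probs,
                background=np.full(4, 0.25) if background is None else np.asarray(background),
                pseudocount=pseudocount,
            )
        )
    return pwms


# -- ground truth ------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    doc = {
        "seed_gene": truth.seed_gene,
        "planted_level": dict(sorted(truth.planted_level.items())),
        "planted_edges": sorted(list(e) for e in truth.planted_edges),
        "planted_motifs": sorted(list(m) for m in truth.planted_motifs),
        "differential_metabolites": sorted(truth.differential_metabolites),
        "metabolite_gene": dict(sorted(truth.metabolite_gene.items())),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(
        seed_gene=doc["seed_gene"],
        planted_level=dict(doc["planted_level"]),
        planted_edges={tuple(e) for e in doc["planted_edges"]},
        planted_motifs={tuple(m) for m in doc["planted_motifs"]},
        differential_metabolites=set(doc["differential_metabolites"]),
        metabolite_gene=dict(doc.get("metabolite_gene", {})),
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a synthetic dataset to a directory; returns the file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metabolites": out / "metabolites.tsv",
        "catalog": out / "catalog.tsv",
        "promoters": out / "promoters.fasta",
        "motifs": out / "motifs.jaspar",
        "truth": out / "truth.yaml",
    }
    write_matrix(dataset.expression, paths["expression"])
    write_matrix(dataset.metabolites, paths["metabolites"])
    write_catalog(dataset.catalog, paths["catalog"])
    write_promoters(dataset.promoters, paths["promoters"])
    write_jaspar(dataset.motifs, paths["motifs"])
    write_truth(dataset.truth, paths["truth"])
    return paths


# -- networks ----------------------------------------------------------------

def write_network(togcn: TOGCN, outdir) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = togcn.graph
    edges = pd.DataFrame(
        [
            {
                "node_u": u,
                "node_v": v,
                "kind_u": g.nodes[u]["kind"],
                "kind_v": g.nodes[v]["kind"],
                "pcc": d["pcc"],
            }
            for u, v, d in g.edges(data=True)
        ]
    )
    nodes = pd.DataFrame(
        [
            {"node": n, "kind": d["kind"], "level": d.get("level")}
            for n, d in g.nodes(data=True)
        ]
    )
    paths = {"edges": out / "edges.tsv", "nodes": out / "nodes.tsv", "graphml": out / "network.graphml"}
    edges.to_csv(paths["edges"], sep="\t", index=False)
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    gx = nx.Graph()
    for n, d in g.nodes(data=True):
        gx.add_node(n, kind=d["kind"], level=-1 if d.get("level") is None else int(d["level"]))
    for u, v, d in g.edges(data=True):
        gx.add_edge(u, v, pcc=float(d["pcc"]))
    nx.write_graphml(gx, paths["graphml"])
    return paths


# -- binding hits ------------------------------------------------------------

def hits_to_bed(hits: Iterable[BindingHit], pwms: Sequence[PWM] = ()) -> str:
    """BED6 lines: chrom = gene id, start/end = the hit window (0-based,
    half-open), score = bits x 100 clipped to [0, 1000]."""
    width = {p.motif_id: p.width for p in pwms}
    lines = []
    for h in hits:
        w_end = h.offset + width.get(h.motif_id, 1)
        score = int(np.clip(h.score * 100, 0, 1000))
        lines.append(f"{h.gene_id}\t{h.offset}\t{w_end}\t{h.motif_id}\t{score}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_hits(hits: Sequence[BindingHit], path, pwms: Sequence[PWM] | None = None) -> None:
    width = {p.motif_id: p.width for p in pwms} if pwms else {}
    df = pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "motif_id": h.motif_id,
                "strand": h.strand,
                "offset": h.offset,
                "end": h.offset + width.get(h.motif_id, 0),
                "score_bits": h.score,
                "p_value": h.p_value,
            }
            for h in hits
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# -- Ks / dating -------------------------------------------------------------

def read_ks(path) -> np.ndarray:
    """One- or two-column (pair_id, ks) tab-separated Ks values."""
    df = pd.read_csv(path, sep="\t", header=None)
    col = df.columns[-1]
    return pd.to_numeric(df[col], errors="coerce").dropna().to_numpy()


def write_dating_report(dating: WGDDating, peaks: Sequence[float], path) -> None:
    doc = {
        "peaks": [float(p) for p in peaks],
        "gamma_per_my": float(dating.gamma),
        "ks_divergence": float(dating.ks_divergence),
        "t_divergence_mya": float(dating.t_divergence),
        "ks_wgd": float(dating.ks_wgd),
        "age_wgd_mya": float(dating.age_wgd),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
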