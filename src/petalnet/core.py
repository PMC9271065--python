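"""Core data containers for staged multi-omics of opening flowers.

The study design behind this package is a four-stage flower-opening time
course (stages ``T1``..``T4``: bud, initial opening, full opening, fading),
each stage sampled with biological replicates.  Expression is carried as an
FPKM matrix (genes x samples), metabolite relative contents as a parallel
matrix over the same samples, and gene roles (transcription-factor family or
flavonoid-pathway enzyme class) in a :class:`GeneCatalog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("T1", "T2", "T3", "T4")

#: Enzyme classes of the flavonol / anthocyanin biosynthesis pathway, in
#: pathway order from phenylalanine ammonia-lyase to rhamnosyltransferase.
ENZYME_CLASSES: tuple[str, ...] = (
    "PAL", "C4H", "4CL", "CHS", "CHI", "F3H", "F3'H|F3'5'H",
    "FLS", "DFR", "ANS", "F3oGT", "RT",
)

COMPOUND_CLASSES: tuple[str, ...] = ("anthocyanin", "flavonol", "other")


@dataclass(frozen=True, order=True)
class OmicsSample:
    """One biological sample: a (stage, replicate) pair with a unique id."""

    sample_id: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


def validate_samples(samples: Sequence[OmicsSample], min_replicates: int = 2) -> None:
    """Check (stage, replicate) uniqueness and per-stage replication."""
    pairs = [(s.stage, s.replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (stage, replicate) pairs in sample sheet")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    counts: dict[str, int] = {}
    for s in samples:
        counts[s.stage] = counts.get(s.stage, 0) + 1
    for stage, n in counts.items():
        if n < min_replicates:
            raise ValueError(f"stage {stage} has {n} replicate(s); need >= {min_replicates}")


class _FeatureMatrix:
    """Shared behaviour of the expression and metabolite matrices.

    ``values`` is a features x samples DataFrame whose columns follow the
    order of ``samples``; all entries must be finite and non-negative.
    """

    values: pd.DataFrame
    samples: tuple[OmicsSample, ...]

    def _validate(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("matrix columns must match sample ids, in order")
        if self.values.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("matrix contains non-finite entries")
        if np.any(vals < 0):
            raise ValueError("matrix contains negative entries")
        validate_samples(self.samples, min_replicates=1)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def stages_present(self) -> list[str]:
        seen = {s.stage for s in self.samples}
        return [st for st in STAGES if st in seen]

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.stage == stage]


@dataclass
class ExpressionMatrix(_FeatureMatrix):
    """FPKM values for genes over staged, replicated samples."""

    values: pd.DataFrame
    samples: tuple[OmicsSample, ...]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self._validate()

    @property
    def gene_ids(self) -> list[str]:
        return self.feature_ids


@dataclass
class MetaboliteMatrix(_FeatureMatrix):
    """Relative contents of flavonoid metabolites over the same samples."""

    values: pd.DataFrame
    samples: tuple[OmicsSample, ...]
    compound_class: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self._validate()
        for mid, cls in self.compound_class.items():
            if cls not in COMPOUND_CLASSES:
                raise ValueError(f"unknown compound class {cls!r} for {mid}")

    @property
    def metabolite_ids(self) -> list[str]:
        return self.feature_ids


@dataclass
class GeneCatalog:
    """Role of each gene: TF (with family), pathway enzyme (with class), or other.

    Roles are stored as ``("tf", family)``, ``("enzyme", cls)`` or
    ``("other", "")``; enzyme classes are restricted to :data:`ENZYME_CLASSES`.
    """

    role: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for gene, (kind, detail) in self.role.items():
            if kind == "enzyme":
                if detail not in ENZYME_CLASSES:
                    raise ValueError(f"unknown enzyme class {detail!r} for {gene}")
            elif kind == "tf":
                if not detail:
                    raise ValueError(f"TF {gene} needs a family name")
            elif kind != "other":
                raise ValueError(f"unknown role kind {kind!r} for {gene}")

    def is_tf(self, gene: str) -> bool:
        return self.role.get(gene, ("other", ""))[0] == "tf"

    def is_structural(self, gene: str) -> bool:
        return self.role.get(gene, ("other", ""))[0] == "enzyme"

    def tf_family(self, gene: str) -> str | None:
        kind, detail = self.role.get(gene, ("other", ""))
        return detail if kind == "tf" else None

    def enzyme_class(self, gene: str) -> str | None:
        kind, detail = self.role.get(gene, ("other", ""))
        return detail if kind == "enzyme" else None

    def node_kind(self, gene: str) -> str:
        """Network node kind: ``tf``, ``structural_gene`` or ``other``."""
        kind = self.role.get(gene, ("other", ""))[0]
        return {"tf": "tf", "enzyme": "structural_gene"}.get(kind, "other")

    def genes(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.role)
        return [g for g, (k, _) in self.role.items() if k == kind]


def make_sample_sheet(n_replicates: int = 3) -> tuple[OmicsSample, ...]:
    """The standard design: every stage T1..T4 with ``n_replicates`` replicates."""
    return tuple(
        OmicsSample(f"{stage}_R{rep}", stage, rep)
        for stage in STAGES
        for rep in range(1, n_replicates + 1)
    )
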