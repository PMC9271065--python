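"""Synthetic staged multi-omics with a planted time-ordered regulatory cascade.

The generator emulates the data structure of a four-stage flower-opening
study: a seed transcription factor (a MYB, highly expressed in buds and
monotonically decreasing to the fading stage) sits at level 1 of a planted
cascade; the remaining TFs and the flavonoid-pathway structural genes occupy
levels 2..k, two levels peaking at each stage; metabolites respond
monotonically to their producing enzymes; and promoters of regulated genes
carry planted binding-site instances for the motif of each true regulator's
TF family.

Every quantity downstream of :func:`generate_timecourse` is therefore
checkable against the returned :class:`SyntheticTruth`.

Geometry of the planted levels
------------------------------
With four stages, centered expression profiles live in a 3-dimensional
space.  Mean FPKM profiles are ``scale * base_fpkm * exp(amplitude * q)``
with ``q`` one of eight unit anchor vectors below, chosen by constrained
optimization (frozen here as constants) so that, on the log10(FPKM+1)
scale the network uses for its correlations,

* adjacent levels correlate at PCC ~0.923 — above the 0.90 gene-gene edge
  cutoff, so the level-(l-1) -> level-l edges that carry the breadth-first
  level assignment exist;
* levels two apart correlate at <= 0.78, three or more apart at <= 0.51 —
  safely below the cutoff, so no level-skipping shortcut edges arise;
* peak stages follow the pattern T1,T1,T2,T2,T3,T3,T4,T4 with margin, and
  the level-1 (seed) profile is strictly decreasing T1 -> T4.

More than eight mutually distinguishable levels cannot exist under these
constraints in a four-stage design, hence ``n_levels`` is capped at 8.

Noise is multiplicative log-normal on the mean profile, matching the
positivity and right skew of FPKM data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ENZYME_CLASSES,
    STAGES,
    ExpressionMatrix,
    GeneCatalog,
    MetaboliteMatrix,
    OmicsSample,
    make_sample_sheet,
)
from .motifs import BASES, PWM, PromoterSet, reverse_complement

#: Unit-norm, zero-mean log-scale anchor profiles over (T1, T2, T3, T4), one
#: per level.  On the log10(FPKM+1) scale of the resulting mean profiles,
#: adjacent rows correlate at ~0.923, rows two apart <= 0.78, three+ <= 0.51.
LEVEL_PROFILES = np.array(
    [
        [0.58444489, 0.13111895, 0.08108947, -0.79665331],
        [0.31204841, 0.27680922, 0.27680922, -0.86566685],
        [-0.00403035, 0.42724752, 0.39166868, -0.81488585],
        [-0.34238276, 0.50720273, 0.47073404, -0.63555401],
        [-0.63555401, 0.47073404, 0.50720273, -0.34238276],
        [-0.81488585, 0.39166868, 0.42724752, -0.00403035],
        [-0.86566685, 0.27680922, 0.27680922, 0.31204841],
        [-0.80030435, -0.04383791, 0.39654562, 0.44759664],
    ]
)

TF_FAMILIES = ("MYB", "bHLH", "WD40", "WRKY", "ERF", "GATA")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic time course.

    Defaults mirror the emulated study: 4 stages x 3 replicates, 8
    time-ordered levels, 2 kb promoters.  ``noise_sd`` is the standard
    deviation of the multiplicative log-normal replicate noise (natural-log
    scale); replicate-level dispersion is not reported for the real data,
    so it is a free parameter.
    """

    n_tf: int
    n_structural: int
    n_metabolites: int
    n_null_metabolites: int | None = None  # default: as many as planted ones
    n_levels: int = 8
    noise_sd: float = 0.1
    edge_density: float = 1.0
    motif_width: int = 10
    promoter_length: int = 2000
    rng_seed: int = 0
    n_replicates: int = 3
    base_fpkm: float = 30.0
    amplitude: float = 2.5
    gene_scale_sd: float = 0.4

    def __post_init__(self) -> None:
        if min(self.n_tf, self.n_structural, self.n_metabolites) <= 0:
            raise ConfigurationError("feature counts must be positive")
        if not 2 <= self.n_levels <= LEVEL_PROFILES.shape[0]:
            raise ConfigurationError(
                f"n_levels must be in [2, {LEVEL_PROFILES.shape[0]}]: a 4-stage design "
                "cannot carry more mutually distinguishable levels"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 < self.edge_density <= 1:
            raise ConfigurationError("edge_density must be in (0, 1]")
        if self.promoter_length < self.motif_width:
            raise ConfigurationError("motif wider than promoter")
        if self.n_replicates < 2:
            raise ConfigurationError("need >= 2 replicates per stage")
        if self.n_tf < self.n_levels:
            raise ConfigurationError("need at least one TF per level (n_tf >= n_levels)")
        if self.amplitude <= 0 or self.base_fpkm <= 0:
            raise ConfigurationError("amplitude and base_fpkm must be positive")
        if self.n_null_metabolites is None:
            self.n_null_metabolites = self.n_metabolites
        if self.n_null_metabolites < 0:
            raise ConfigurationError("n_null_metabolites must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``planted_edges`` holds (regulator, target) pairs: TF -> TF links one
    level apart, TF -> structural-gene links at the same or the previous
    level, and enzyme -> metabolite links.  ``planted_motifs`` records every
    motif instance placed in a promoter as (gene, motif_id, offset, strand).
    """

    seed_gene: str
    planted_level: dict[str, int]
    planted_edges: set[tuple[str, str]]
    planted_motifs: set[tuple[str, str, int, str]]
    differential_metabolites: set[str]
    metabolite_gene: dict[str, str] = field(default_factory=dict)

    def regulator_edges(self) -> set[tuple[str, str]]:
        """Planted TF -> structural-gene edges only."""
        return {
            (r, t) for (r, t) in self.planted_edges if t.startswith("SG")
        }


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    metabolites: MetaboliteMatrix
    catalog: GeneCatalog
    promoters: PromoterSet
    motifs: list[PWM]
    truth: SyntheticTruth
    config: SimConfig


def _level_assignments(cfg: SimConfig) -> dict[str, int]:
    """Gene id -> planted level.  The seed TF is the only level-1 node;
    other TFs fill levels 2..k round-robin, structural genes likewise
    (starting at level 3 when available, as pathway genes lag their
    regulators)."""
    levels: dict[str, int] = {"TF001": 1}
    tf_levels = list(range(2, cfg.n_levels + 1))
    for i in range(1, cfg.n_tf):
        levels[f"TF{i + 1:03d}"] = tf_levels[(i - 1) % len(tf_levels)]
    sg_start = 3 if cfg.n_levels >= 3 else 2
    sg_levels = list(range(sg_start, cfg.n_levels + 1))
    for i in range(cfg.n_structural):
        levels[f"SG{i + 1:03d}"] = sg_levels[i % len(sg_levels)]
    return levels


def _mean_profiles(levels: dict[str, int], cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = {}
    for gene, lvl in levels.items():
        scale = float(np.exp(rng.normal(0.0, cfg.gene_scale_sd)))
        rows[gene] = scale * cfg.base_fpkm * np.exp(cfg.amplitude * LEVEL_PROFILES[lvl - 1])
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STAGES))


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm.probs[:, c] / pwm.probs[:, c].sum()) for c in range(pwm.width)]
    return "".join(BASES[b] for b in cols)


def generate_timecourse(cfg: SimConfig) -> SyntheticDataset:
    """Generate one staged multi-omics dataset with known ground truth.

    Deterministic given ``cfg.rng_seed``: one :class:`numpy.random.Generator`
    drives all randomness.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    samples = make_sample_sheet(cfg.n_replicates)

    # -- catalog -------------------------------------------------------------
    role: dict[str, tuple[str, str]] = {"TF001": ("tf", "MYB")}
    for i in range(1, cfg.n_tf):
        role[f"TF{i + 1:03d}"] = ("tf", TF_FAMILIES[i % len(TF_FAMILIES)])
    for i in range(cfg.n_structural):
        role[f"SG{i + 1:03d}"] = ("enzyme", ENZYME_CLASSES[i % len(ENZYME_CLASSES)])
    catalog = GeneCatalog(role)

    levels = _level_assignments(cfg)
    means = _mean_profiles(levels, cfg, rng)

    # -- expression values ----------------------------------------------------
    stage_idx = {s.sample_id: STAGES.index(s.stage) for s in samples}
    expr = pd.DataFrame(
        0.0, index=means.index, columns=[s.sample_id for s in samples]
    )
    noise = rng.normal(0.0, cfg.noise_sd, size=expr.shape) if cfg.noise_sd > 0 else 0.0
    base = means.to_numpy()[:, [stage_idx[c] for c in expr.columns]]
    expr.iloc[:, :] = base * np.exp(noise)
    expression = ExpressionMatrix(expr, samples)

    # -- metabolites: monotone (linear) responses to their producing enzyme,
    # plus stage-independent null metabolites that should fail the screen ----
    metab_gene: dict[str, str] = {}
    sg_ids = [f"SG{i + 1:03d}" for i in range(cfg.n_structural)]
    mrows = {}
    classes = {}
    class_cycle = ("anthocyanin", "flavonol", "other")
    for i in range(cfg.n_metabolites):
        mid = f"M{i + 1:03d}"
        gene = sg_ids[i % len(sg_ids)]
        metab_gene[mid] = gene
        classes[mid] = class_cycle[i % 3]
        gain = float(np.exp(rng.normal(0.0, cfg.gene_scale_sd)))
        mnoise = rng.normal(0.0, cfg.noise_sd, size=len(samples)) if cfg.noise_sd > 0 else 0.0
        mrows[mid] = gain * base[means.index.get_loc(gene)] * np.exp(mnoise)
        levels[mid] = levels[gene]
    for i in range(cfg.n_null_metabolites):
        mid = f"MN{i + 1:03d}"
        level_mean = float(cfg.base_fpkm * np.exp(rng.normal(0.0, cfg.gene_scale_sd)))
        mnoise = rng.normal(0.0, cfg.noise_sd, size=len(samples)) if cfg.noise_sd > 0 else 0.0
        mrows[mid] = level_mean * np.exp(np.asarray(mnoise) + np.zeros(len(samples)))
        classes[mid] = "other"
    metab = pd.DataFrame.from_dict(mrows, orient="index")
    metab.columns = [s.sample_id for s in samples]
    metabolites = MetaboliteMatrix(metab, samples, classes)

    # -- planted regulatory edges ---------------------------------------------
    by_level: dict[int, list[str]] = {}
    for g in role:
        by_level.setdefault(levels[g], []).append(g)
    tf_at = {
        lvl: [g for g in gs if catalog.is_tf(g)] for lvl, gs in by_level.items()
    }
    planted: set[tuple[str, str]] = set()
    for target, lvl in list(levels.items()):
        if target.startswith("M"):
            planted.add((metab_gene[target], target))
            continue
        if lvl == 1:
            continue
        if catalog.is_tf(target):
            candidates = [r for r in tf_at.get(lvl - 1, []) if r != target]
        else:  # structural gene: same-level and previous-level TFs
            candidates = list(tf_at.get(lvl - 1, [])) + list(tf_at.get(lvl, []))
        for reg in candidates:
            if cfg.edge_density >= 1.0 or rng.random() < cfg.edge_density:
                planted.add((reg, target))

    # -- motifs: one PWM per TF family ----------------------------------------
    pwms: list[PWM] = []
    family_pwm: dict[str, PWM] = {}
    for fam in TF_FAMILIES:
        consensus = rng.choice(4, size=cfg.motif_width)
        probs = np.full((4, cfg.motif_width), 0.05 / 3)
        probs[consensus, np.arange(cfg.motif_width)] = 0.95
        pwm = PWM(motif_id=f"{fam}.1", tf_family=fam, probs=probs)
        pwms.append(pwm)
        family_pwm[fam] = pwm

    # -- promoters with planted sites for true regulators ---------------------
    targets_of: dict[str, set[str]] = {}
    for reg, tgt in planted:
        if tgt.startswith("M"):
            continue
        fam = catalog.tf_family(reg)
        if fam is not None:
            targets_of.setdefault(tgt, set()).add(fam)
    sequences: dict[str, str] = {}
    planted_motifs: set[tuple[str, str, int, str]] = set()
    w = cfg.motif_width
    for gene in role:
        seq = rng.choice(4, size=cfg.promoter_length)
        occupied: list[tuple[int, int]] = []
        for fam in sorted(targets_of.get(gene, ())):
            pwm = family_pwm[fam]
            for _ in range(100):
                off = int(rng.integers(0, cfg.promoter_length - w + 1))
                if all(off + w <= a or off >= b for a, b in occupied):
                    break
            else:  # pragma: no cover - promoters are never that crowded
                continue
            occupied.append((off, off + w))
            site = _sample_site(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else reverse_complement(site)
            seq[off : off + w] = [BASES.index(b) for b in placed]
            planted_motifs.add((gene, pwm.motif_id, off, strand))
        sequences[gene] = "".join(BASES[b] for b in seq)
    promoters = PromoterSet(sequences)

    truth = SyntheticTruth(
        seed_gene="TF001",
        planted_level=dict(levels),
        planted_edges=planted,
        planted_motifs=planted_motifs,
        differential_metabolites=set(metab_gene),
        metabolite_gene=metab_gene,
    )
    return SyntheticDataset(expression, metabolites, catalog, promoters, pwms, truth, cfg)
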