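"""Differential screening of genes and metabolites across flower-opening stages.

Genes are called differentially expressed when they are expressed at all
(mean FPKM > 0.5), change at least two-fold between some pair of stage
means (|log2 FC| >= 1) and a per-gene one-way ANOVA across the four stages
on log10(FPKM + 1) values is significant after Benjamini-Hochberg
correction (FDR < 0.05).  Metabolites are called differential when their
extreme stage-mean fold change exceeds 2 (or falls below 0.5) and their
variable importance in projection (VIP) from a PLS-DA of stage membership
exceeds 1.

Also houses the small transforms used around the screen: log10(x+1),
the 2^-ddCt relative-expression statistic for qPCR, relative shares of
compound contents, and a PCA of differential metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .core import STAGES, ExpressionMatrix, MetaboliteMatrix, _FeatureMatrix


@dataclass
class ScreenConfig:
    """Thresholds of the differential screens.

    All inequalities are applied exactly as stated: FC > ``fc_up`` or
    FC < ``fc_down``; VIP > ``vip_min`` (strict); adjusted p < ``fdr_max``;
    |log2 FC| >= ``lfc_min``; mean FPKM > ``fpkm_min``.  ``pseudocount`` is
    added to both stage means before any ratio.
    """

    fc_up: float = 2.0
    fc_down: float = 0.5
    vip_min: float = 1.0
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    fpkm_min: float = 0.5
    n_pls_components: int = 2
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not self.fc_up > 1 > self.fc_down > 0:
            raise ValueError("need fc_up > 1 > fc_down > 0")
        for name in ("vip_min", "fdr_max", "lfc_min", "fpkm_min", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_pls_components < 1:
            raise ValueError("n_pls_components must be >= 1")


def log_transform(x):
    """log10(x + 1); maps 0 to 0 and is monotone on x >= 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform requires non-negative input")
    out = np.log10(arr + 1.0)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def stage_means(matrix: _FeatureMatrix) -> pd.DataFrame:
    """Arithmetic mean over replicates of each stage (features x stages)."""
    stages = matrix.stages_present()
    if not stages:
        raise ValueError("no stages present")
    cols = {}
    for stage in stages:
        ids = matrix.samples_of_stage(stage)
        if not ids:
            raise ValueError(f"stage {stage} has no samples")
        cols[stage] = matrix.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def _best_log2fc(means: pd.DataFrame, pseudocount: float) -> pd.Series:
    """Signed log2 fold change of the most extreme stage pair per feature.

    For every ordered stage pair (earlier a, later b), the fold change is
    (mean_b + pc) / (mean_a + pc); the value with the largest magnitude of
    log2 is reported with its sign.
    """
    m = means.to_numpy() + pseudocount
    stages = list(means.columns)
    best = np.zeros(len(means))
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            lfc = np.log2(m[:, j] / m[:, i])
            take = np.abs(lfc) > np.abs(best)
            best = np.where(take, lfc, best)
    return pd.Series(best, index=means.index)


def de_genes(expr: ExpressionMatrix, cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Per-gene differential-expression screen across the stages.

    Returns a DataFrame with the stage means, ``mean_fpkm``, signed
    ``log2fc`` of the extreme stage pair, raw and BH-``adjusted_p`` from a
    one-way ANOVA on log10(FPKM+1), and the boolean ``passes`` call.
    """
    cfg = cfg or ScreenConfig()
    stages = expr.stages_present()
    if len(stages) < 2:
        raise ValueError("need at least 2 stages for a differential screen")
    for stage in stages:
        if len(expr.samples_of_stage(stage)) < 2:
            raise ValueError(f"stage {stage} has < 2 replicates")
    means = stage_means(expr)
    logged = log_transform(expr.values.to_numpy())
    groups = [
        logged[:, [expr.values.columns.get_loc(c) for c in expr.samples_of_stage(st)]]
        for st in stages
    ]
    with warnings.catch_warnings():
        # constant genes yield an undefined F statistic; they are non-DE
        warnings.simplefilter("ignore")
        f_stat, pvals = stats.f_oneway(*groups, axis=1)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    out = means.copy()
    out["mean_fpkm"] = expr.values.mean(axis=1)
    out["log2fc"] = _best_log2fc(means, cfg.pseudocount)
    out["p_value"] = pvals
    out["adjusted_p"] = adjusted
    out["passes"] = (
        (out["mean_fpkm"] > cfg.fpkm_min)
        & (out["log2fc"].abs() >= cfg.lfc_min)
        & (out["adjusted_p"] < cfg.fdr_max)
    )
    return out


def pls_vip(
    metab: MetaboliteMatrix,
    class_labels: Sequence[str] | None = None,
    n_components: int = 2,
) -> pd.Series:
    """Variable importance in projection from a PLS-DA of sample groups.

    The response is the one-hot group membership (by default the stage of
    each sample); predictors are the metabolites, centered and scaled to
    unit variance.  VIP_j = sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a) with
    w_a the unit x-weights and SS_a the response variance explained by
    component a; sum_j VIP_j^2 = p by construction.
    """
    X = metab.values.to_numpy().T  # samples x metabolites
    labels = list(class_labels) if class_labels is not None else [s.stage for s in metab.samples]
    if len(labels) != X.shape[0]:
        raise ValueError("one class label per sample required")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    for g in uniq:
        if labels.count(g) < 2:
            raise ValueError(f"group {g} has < 2 samples")
    if X.shape[0] <= n_components:
        raise ValueError("fewer samples than PLS components")
    Y = np.array([[1.0 if lab == g else 0.0 for g in uniq] for lab in labels])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant metabolites are tolerated
        pls = PLSRegression(n_components=n_components, scale=True, max_iter=20000, tol=1e-18)
        pls.fit(X, Y)
    W = pls.x_weights_  # p x A, unit columns
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # m x A
    ss = np.einsum("na,na->a", T, T) * np.einsum("ma,ma->a", Q, Q)
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0), 1e-300)
    p = X.shape[1]
    vip = np.sqrt(p * (wnorm2 * ss).sum(axis=1) / ss.sum())
    return pd.Series(vip, index=metab.metabolite_ids, name="vip")


def de_metabolites(metab: MetaboliteMatrix, cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Differential-metabolite screen: extreme stage-mean fold change and VIP.

    The fold change is taken between the extreme stage-mean pair (the
    maximum and minimum over all ordered pairs); a metabolite passes when
    FC > ``fc_up`` or FC < ``fc_down`` and VIP > ``vip_min`` (strict).
    """
    cfg = cfg or ScreenConfig()
    means = stage_means(metab)
    m = means.to_numpy() + cfg.pseudocount
    fc_max = np.ones(len(means))
    fc_min = np.ones(len(means))
    k = m.shape[1]
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            fc = m[:, j] / m[:, i]
            fc_max = np.maximum(fc_max, fc)
            fc_min = np.minimum(fc_min, fc)
    vip = pls_vip(metab, n_components=cfg.n_pls_components)
    out = means.copy()
    out["fc_max"] = fc_max
    out["fc_min"] = fc_min
    out["vip"] = vip
    out["passes"] = ((out["fc_max"] > cfg.fc_up) | (out["fc_min"] < cfg.fc_down)) & (
        out["vip"] > cfg.vip_min
    )
    return out


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values of target and reference genes in test and calibrator samples."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for f in (
            self.ct_target_test,
            self.ct_reference_test,
            self.ct_target_calibrator,
            self.ct_reference_calibrator,
        ):
            if not np.isfinite(f):
                raise ValueError("Ct values must be finite")


def ddct(m: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method."""
    dd = (m.ct_target_test - m.ct_reference_test) - (
        m.ct_target_calibrator - m.ct_reference_calibrator
    )
    return float(2.0 ** (-dd))


def relative_share(contents: Sequence[float]) -> np.ndarray:
    """Each content as a percentage of the subset total; sums to 100."""
    arr = np.asarray(contents, dtype=float)
    if np.any(arr < 0):
        raise ValueError("contents must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("at least one content must be positive")
    return 100.0 * arr / total


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # metabolites x components
    variance_fractions: np.ndarray
    dropped: list[str]


def metabolite_pca(
    metab: MetaboliteMatrix,
    subset: Sequence[str] | None = None,
    scale: bool = True,
) -> PCAResult:
    """PCA of the samples over a metabolite subset, for the screen's biplot.

    Metabolites are centered and (by default) scaled to unit variance;
    constant metabolites are dropped with a warning.  Variance fractions
    over all retained components sum to 1.
    """
    ids = list(subset) if subset is not None else metab.metabolite_ids
    if not ids:
        raise ValueError("subset must be non-empty")
    if len(metab.samples) < 3:
        raise ValueError("need >= 3 samples for a PCA")
    X = metab.values.loc[ids].to_numpy().T  # samples x metabolites
    sd = X.std(axis=0, ddof=1)
    dropped = [ids[i] for i in np.nonzero(sd == 0)[0]]
    if dropped:
        warnings.warn(f"dropping constant metabolites: {dropped}")
        keep = sd > 0
        X = X[:, keep]
        ids = [m for m, k in zip(ids, keep) if k]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(X)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=[s.sample_id for s in metab.samples], columns=comps),
        loadings=pd.DataFrame(pca.components_.T, index=ids, columns=comps),
        variance_fractions=pca.explained_variance_ratio_,
        dropped=dropped,
    )
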