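"""Differential screens, VIP, qPCR and share transforms against oracles."""

import numpy as np
import pandas as pd
import pytest

import petalnet as pn
from conftest import matrix_from


# -- independent oracles ------------------------------------------------------

def nipals_vip_oracle(X, Y, n_components, tol=1e-10):
    """Step-by-step NIPALS PLS2 on centered, unit-variance data."""
    X = np.asarray(X, float).copy()
    Y = np.asarray(Y, float).copy()
    X -= X.mean(0)
    Y -= Y.mean(0)
    xs = X.std(0, ddof=1)
    xs[xs == 0] = 1.0
    X /= xs
    ys = Y.std(0, ddof=1)
    ys[ys == 0] = 1.0
    Y /= ys
    p = X.shape[1]
    W, T, Q = [], [], []
    Xr, Yr = X.copy(), Y.copy()
    for _ in range(n_components):
        u = Yr[:, 0].copy()
        w_old = None
        for _ in range(200000):
            w = Xr.T @ u
            w /= np.linalg.norm(w)
            t = Xr @ w
            q = Yr.T @ t / (t @ t)
            u = Yr @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        pload = Xr.T @ t / (t @ t)
        Xr = Xr - np.outer(t, pload)
        Yr = Yr - np.outer(t, q)
        W.append(w)
        T.append(t)
        Q.append(q)
    W, T, Q = (np.array(a).T for a in (W, T, Q))
    ss = (T**2).sum(0) * (Q**2).sum(0)
    return np.sqrt(p * ((W**2) * ss).sum(1) / ss.sum())


def one_hot(labels):
    uniq = sorted(set(labels))
    return np.array([[1.0 if lab == g else 0.0 for g in uniq] for lab in labels])


# -- stage means and small transforms ----------------------------------------

def test_stage_means_matches_loop_oracle(study):
    sm = pn.stage_means(study.expression)
    for gene in study.expression.gene_ids[:10]:
        for stage in pn.STAGES:
            ids = study.expression.samples_of_stage(stage)
            expected = np.mean([study.expression.values.loc[gene, c] for c in ids])
            assert sm.loc[gene, stage] == pytest.approx(expected, rel=1e-12)


def test_stage_means_simple_cases(samples12):
    vals = np.ones((1, 12))
    vals[0, :3] = [0.0, 3.0, 3.0]  # T1 replicates
    expr = pn.ExpressionMatrix(matrix_from(vals, samples12, "G"), samples12)
    sm = pn.stage_means(expr)
    assert sm.loc["G001", "T1"] == pytest.approx(2.0)
    assert sm.loc["G001", "T2"] == pytest.approx(1.0)


@pytest.mark.parametrize("x,expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
def test_log_transform_values(x, expected):
    assert pn.log_transform(x) == pytest.approx(expected)


def test_log_transform_rejects_negative():
    with pytest.raises(ValueError):
        pn.log_transform(-1.0)


@pytest.mark.parametrize(
    "cts,expected",
    [
        ((20, 18, 20, 18), 1.0),  # ddCt = 0
        ((19, 18, 20, 18), 2.0),  # one-cycle advantage doubles
        ((20, 18, 24, 18), 16.0),  # 2^-(2-6)
    ],
)
def test_ddct(cts, expected):
    assert pn.ddct(pn.QpcrMeasurement(*cts)) == pytest.approx(expected)


def test_relative_share():
    assert pn.relative_share([5, 5]) == pytest.approx([50.0, 50.0])
    assert pn.relative_share([1, 0]) == pytest.approx([100.0, 0.0])
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 10, 25)
    assert pn.relative_share(vals).sum() == pytest.approx(100.0, abs=1e-9)
    with pytest.raises(ValueError):
        pn.relative_share([0.0, 0.0])


# -- gene screen --------------------------------------------------------------

def test_constant_gene_fails_screen(samples12):
    vals = np.vstack([np.full(12, 5.0), np.r_[np.full(3, 1.0), np.full(9, 8.0)]])
    expr = pn.ExpressionMatrix(matrix_from(vals, samples12, "G"), samples12)
    res = pn.de_genes(expr)
    assert not res.loc["G001", "passes"]  # constant: log2FC = 0
    assert res.loc["G001", "log2fc"] == pytest.approx(0.0)


def test_low_abundance_gene_fails_on_fpkm_filter(samples12):
    # 10-fold stage change but overall mean FPKM 0.4 < 0.5
    profile = np.r_[np.full(3, 0.94), np.full(3, 0.094), np.full(3, 0.283), np.full(3, 0.283)]
    rng = np.random.default_rng(1)
    vals = np.vstack([profile * np.exp(rng.normal(0, 0.01, 12)) for _ in range(3)])
    expr = pn.ExpressionMatrix(matrix_from(vals, samples12, "G"), samples12)
    res = pn.de_genes(expr)
    assert np.all(res["mean_fpkm"] < 0.5)
    assert not res["passes"].any()


def test_planted_de_genes_recovered_with_fdr_control(samples12):
    """20 planted four-fold genes among 200 nulls: >= 90% sensitivity and
    an empirical false-positive rate within the nominal FDR + 0.05."""
    rng = np.random.default_rng(7)
    n_null, n_de = 200, 20
    null = 10.0 * np.exp(rng.normal(0, 0.1, size=(n_null, 12)))
    profile = np.r_[np.full(3, 4.0), np.full(3, 1.0), np.full(3, 1.0), np.full(3, 4.0)]
    de = 5.0 * profile * np.exp(rng.normal(0, 0.1, size=(n_de, 12)))
    expr = pn.ExpressionMatrix(matrix_from(np.vstack([null, de]), samples12, "G"), samples12)
    res = pn.de_genes(expr)
    de_ids = [f"G{i + 1:03d}" for i in range(n_null, n_null + n_de)]
    null_ids = [f"G{i + 1:03d}" for i in range(n_null)]
    sensitivity = res.loc[de_ids, "passes"].mean()
    fpr = res.loc[null_ids, "passes"].mean()
    assert sensitivity >= 0.9
    assert fpr <= 0.05 + 0.05


def test_screen_invariant_to_replicate_permutation(study):
    expr = study.expression
    res1 = pn.de_genes(expr)
    # permute replicate columns within every stage
    order = []
    for stage in pn.STAGES:
        ids = expr.samples_of_stage(stage)
        order.extend([ids[1], ids[2], ids[0]])
    permuted = pn.ExpressionMatrix(
        expr.values[order].set_axis([s.sample_id for s in expr.samples], axis=1),
        expr.samples,
    )
    # relabel columns back to canonical ids: same stage groups, shuffled reps
    res2 = pn.de_genes(permuted)
    assert np.allclose(res1["adjusted_p"], res2["adjusted_p"])
    assert (res1["passes"] == res2["passes"]).all()


def test_bh_adjustment_is_monotone_in_rank(study):
    res = pn.de_genes(study.expression)
    df = res.sort_values("p_value")
    assert np.all(np.diff(df["adjusted_p"]) >= -1e-12)


# -- VIP ----------------------------------------------------------------------

def test_vip_matches_nipals_oracle(samples12):
    rng = np.random.default_rng(3)
    X = np.abs(rng.normal(size=(12, 5))) + 0.5
    metab = pn.MetaboliteMatrix(matrix_from(X.T, samples12, "M"), samples12)
    labels = [s.stage for s in samples12]
    expected = nipals_vip_oracle(X, one_hot(labels), 2)
    got = pn.pls_vip(metab, n_components=2).to_numpy()
    assert np.allclose(got, expected, atol=1e-8)


def test_vip_sum_of_squares_equals_p(study):
    vip = pn.pls_vip(study.metabolites, n_components=2)
    assert (vip**2).sum() == pytest.approx(len(vip), abs=1e-8)


def test_vip_single_component_uniform_weights(samples12):
    """Metabolites that are exact copies of one latent profile share the
    weight equally, so every VIP is 1."""
    latent = np.r_[np.full(3, 1.0), np.full(3, 2.0), np.full(3, 3.0), np.full(3, 4.0)]
    X = np.vstack([latent, latent, latent, latent])
    metab = pn.MetaboliteMatrix(matrix_from(X, samples12, "M"), samples12)
    vip = pn.pls_vip(metab, n_components=1)
    assert np.allclose(vip, 1.0, atol=1e-10)


def test_vip_zero_weight_metabolite(samples12):
    """A constant metabolite gets weight 0 on the retained component."""
    latent = np.r_[np.full(3, 1.0), np.full(3, 2.0), np.full(3, 3.0), np.full(3, 4.0)]
    X = np.vstack([latent, np.full(12, 5.0)])
    metab = pn.MetaboliteMatrix(matrix_from(X, samples12, "M"), samples12)
    vip = pn.pls_vip(metab, n_components=1)
    assert vip.iloc[1] == pytest.approx(0.0, abs=1e-10)


def test_vip_errors(samples12):
    X = np.abs(np.random.default_rng(0).normal(size=(3, 12))) + 1
    metab = pn.MetaboliteMatrix(matrix_from(X, samples12, "M"), samples12)
    with pytest.raises(ValueError):
        pn.pls_vip(metab, class_labels=["a"] * 12)  # one group
    with pytest.raises(ValueError):
        pn.pls_vip(metab, n_components=12)  # not fewer samples than comps


# -- metabolite screen --------------------------------------------------------

def test_flat_metabolite_fails(samples12):
    latent = np.r_[np.full(3, 1.0), np.full(3, 5.0), np.full(3, 2.0), np.full(3, 4.0)]
    X = np.vstack([np.full(12, 3.0), latent])
    metab = pn.MetaboliteMatrix(matrix_from(X, samples12, "M"), samples12)
    res = pn.de_metabolites(metab)
    assert not res.loc["M001", "passes"]
    assert res.loc["M001", "fc_max"] == pytest.approx(1.0)


def test_vip_exactly_one_fails_strict_inequality():
    """FC = 3 with VIP exactly 1.0 must fail because VIP > 1 is strict."""
    cfg = pn.ScreenConfig()
    fc, vip = 3.0, 1.0
    passes = ((fc > cfg.fc_up) or (fc < cfg.fc_down)) and (vip > cfg.vip_min)
    assert not passes


def test_planted_metabolites_pass_nulls_fail(study):
    res = pn.de_metabolites(study.metabolites)
    planted = sorted(study.truth.differential_metabolites)
    nulls = [m for m in study.metabolites.metabolite_ids if m not in planted]
    assert res.loc[planted, "passes"].all()
    assert res.loc[nulls, "passes"].mean() <= 0.2


# -- PCA ----------------------------------------------------------------------

def test_pca_rank1_and_symmetric_cases(samples12):
    latent = np.r_[np.full(3, 1.0), np.full(3, 2.0), np.full(3, 3.0), np.full(3, 4.0)]
    two_corr = np.vstack([latent, 2 * latent])
    metab = pn.MetaboliteMatrix(matrix_from(two_corr, samples12, "M"), samples12)
    res = pn.metabolite_pca(metab)
    assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    orth = np.vstack([np.tile([1.0, 2.0, 1.0, 2.0], 3), np.repeat([1.0, 2.0], 6)])
    # decorrelate: x varies within pairs, y varies between halves
    metab2 = pn.MetaboliteMatrix(matrix_from(orth, samples12, "M"), samples12)
    res2 = pn.metabolite_pca(metab2)
    if abs(np.corrcoef(orth)[0, 1]) < 1e-12:
        assert res2.variance_fractions[0] == pytest.approx(0.5, abs=1e-12)


def test_pca_matches_eigendecomposition_oracle(samples12):
    rng = np.random.default_rng(11)
    X = np.abs(rng.normal(size=(20, 12))) + 0.2
    metab = pn.MetaboliteMatrix(matrix_from(X, samples12, "M"), samples12)
    res = pn.metabolite_pca(metab, scale=True)
    Z = X.T - X.T.mean(0)
    Z = Z / Z.std(0, ddof=1)
    evals = np.clip(np.linalg.eigvalsh(np.cov(Z.T))[::-1], 0, None)
    k = len(res.variance_fractions)
    assert np.allclose(res.variance_fractions, evals[:k] / evals.sum(), atol=1e-8)
    assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_drops_constant_metabolite(samples12):
    latent = np.r_[np.full(3, 1.0), np.full(3, 2.0), np.full(3, 3.0), np.full(3, 4.0)]
    X = np.vstack([latent, np.full(12, 7.0), 2 * latent])
    metab = pn.MetaboliteMatrix(matrix_from(X, samples12, "M"), samples12)
    with pytest.warns(UserWarning):
        res = pn.metabolite_pca(metab)
    assert res.dropped == ["M002"]
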