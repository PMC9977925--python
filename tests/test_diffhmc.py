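import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from rrhp.diffhmc import (
    bh_adjust,
    call_dhmc,
    differential_analysis,
    ebayes_moderate,
    fit_f_dist,
    make_design,
    mds_coordinates,
    trigamma_inverse,
    voom_transform,
    weighted_lm_fit,
    SiteFit,
)
from conftest import make_matrix


def nb_matrix(seed, n_sites=60, mean_scale=10.0, n=5):
    rng = np.random.default_rng(seed)
    mu = rng.gamma(3.0, mean_scale, n_sites)
    r = 1 / 0.3
    counts = rng.negative_binomial(r, r / (r + np.tile(mu[:, None], (1, 2 * n))))
    return make_matrix(counts, n_large=n, n_small=n)


# ---------------------------------------------------------------- voom


def test_logcpm_closed_form():
    matrix = make_matrix([[0] * 10, [999_999] * 10] + [[10] * 10] * 20)
    v = voom_transform(matrix, np.column_stack([np.ones(10), [1] * 5 + [0] * 5]))
    lib = matrix.counts.sum(axis=0)
    assert lib.iloc[0] > 0
    expected = np.log2(0.5 / (lib.iloc[0] + 1) * 1e6)
    assert v.logcpm.iloc[0, 0] == pytest.approx(expected)
    # closed form: c=0 in a library of size 999,999 -> exactly -1
    assert np.log2((0 + 0.5) / (999_999 + 1) * 1e6) == pytest.approx(-1.0)


def test_weights_are_positive_and_finite():
    v = voom_transform(nb_matrix(0))
    assert np.all(v.weights > 0)
    assert np.all(np.isfinite(v.weights))


def test_constant_counts_hit_the_weight_ceiling():
    matrix = make_matrix([[50] * 10] * 30)
    v = voom_transform(matrix, weight_ceiling=1e6)
    assert np.all(v.weights == 1e6)


def test_zero_library_size_is_an_error():
    matrix = make_matrix([[0, 5, 5, 5, 5, 5, 5, 5, 5, 5]])
    with pytest.raises(ValueError, match="BL1"):
        voom_transform(matrix)


# ---------------------------------------------------------------- WLS


def test_unit_weights_balanced_design_gives_group_mean_difference():
    matrix = nb_matrix(1, n_sites=20)
    design, _ = make_design(matrix.samples)
    v = voom_transform(matrix, design)
    v.weights[:] = 1.0
    fit = weighted_lm_fit(v, design)
    y = v.logcpm.to_numpy()
    expected = y[:, :5].mean(axis=1) - y[:, 5:].mean(axis=1)
    np.testing.assert_allclose(fit.coefficients[:, 1], expected, atol=1e-12)
    assert fit.df_residual == 8


def test_doubling_all_weights_leaves_coefficients_unchanged():
    matrix = nb_matrix(2, n_sites=20)
    design, _ = make_design(matrix.samples)
    v = voom_transform(matrix, design)
    fit1 = weighted_lm_fit(v, design)
    v.weights *= 2.0
    fit2 = weighted_lm_fit(v, design)
    np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, rtol=1e-12)
    np.testing.assert_allclose(fit1.sigma**2 * 2, fit2.sigma**2, rtol=1e-12)


def test_wls_agrees_with_normal_equations_oracle_to_1e8():
    matrix = nb_matrix(3, n_sites=50)
    design, _ = make_design(matrix.samples)
    v = voom_transform(matrix, design)
    fit = weighted_lm_fit(v, design)
    for g in range(50):
        w = np.diag(v.weights[g])
        y = v.logcpm.to_numpy()[g]
        xtwx = design.T @ w @ design
        beta = np.linalg.solve(xtwx, design.T @ w @ y)
        resid = y - design @ beta
        sigma2 = (resid @ w @ resid) / (10 - 2)
        np.testing.assert_allclose(fit.coefficients[g], beta, atol=1e-8)
        assert fit.sigma[g] ** 2 == pytest.approx(sigma2, abs=1e-8)
        assert fit.stdev_unscaled[g] == pytest.approx(
            math.sqrt(np.linalg.inv(xtwx)[1, 1]), abs=1e-8
        )


# ---------------------------------------------------------------- eBayes


def brute_force_hyperparameters(s2, df):
    """Independent root-finding oracle for the moment equations."""
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2)
    if evar <= 0:
        return math.inf, float(np.mean(s2))
    half_d0 = optimize.brentq(lambda x: polygamma(1, x) - evar, 1e-8, 1e8)
    d0 = 2 * half_d0
    s0 = math.exp(emean + digamma(half_d0) - math.log(half_d0))
    return d0, s0


def synthetic_fit(seed, n_sites=50, df=8):
    rng = np.random.default_rng(seed)
    true_s2 = rng.gamma(2.0, 0.5, n_sites)
    s2 = true_s2 * rng.chisquare(df, n_sites) / df
    return SiteFit(
        coefficients=np.column_stack([np.zeros(n_sites), rng.normal(0, 1, n_sites)]),
        stdev_unscaled=np.full(n_sites, math.sqrt(2.0 / 5.0)),
        sigma=np.sqrt(s2),
        df_residual=df,
        index=pd.RangeIndex(n_sites),
    )


def test_hyperparameters_match_independent_root_finding_oracle():
    fit = synthetic_fit(4)
    d0, s0 = fit_f_dist(fit.sigma**2, fit.df_residual)
    d0_ref, s0_ref = brute_force_hyperparameters(fit.sigma**2, fit.df_residual)
    assert d0 == pytest.approx(d0_ref, rel=1e-8)
    assert s0 == pytest.approx(s0_ref, rel=1e-8)


def test_moderated_t_matches_direct_evaluation():
    fit = synthetic_fit(5)
    result = ebayes_moderate(fit)
    d0, s0 = brute_force_hyperparameters(fit.sigma**2, fit.df_residual)
    s2_post = (d0 * s0 + fit.df_residual * fit.sigma**2) / (d0 + fit.df_residual)
    t_ref = fit.coefficients[:, 1] / (np.sqrt(s2_post) * fit.stdev_unscaled)
    p_ref = 2 * stats.t.sf(np.abs(t_ref), d0 + fit.df_residual)
    np.testing.assert_allclose(result.table["t"], t_ref, rtol=1e-8)
    np.testing.assert_allclose(result.table["p"], p_ref, rtol=1e-8)


def test_posterior_variance_lies_between_sample_and_prior():
    fit = synthetic_fit(6)
    result = ebayes_moderate(fit)
    s2 = fit.sigma**2
    lo = np.minimum(s2, result.s0_sq)
    hi = np.maximum(s2, result.s0_sq)
    assert np.all(result.table["s2_post"] >= lo - 1e-12)
    assert np.all(result.table["s2_post"] <= hi + 1e-12)


def test_infinite_prior_df_shrinks_every_variance_to_the_prior():
    fit = synthetic_fit(7)
    result = ebayes_moderate(fit, d0=math.inf, s0_sq=0.7)
    assert np.all(result.table["s2_post"] == 0.7)


def test_zero_prior_df_reproduces_the_ordinary_t():
    fit = synthetic_fit(8)
    result = ebayes_moderate(fit, d0=0.0, s0_sq=1.0)
    t_ord = fit.coefficients[:, 1] / (fit.sigma * fit.stdev_unscaled)
    np.testing.assert_allclose(result.table["t"], t_ord, rtol=1e-12)


def test_fewer_than_two_variances_cannot_be_moderated():
    fit = synthetic_fit(9, n_sites=1)
    with pytest.raises(ValueError, match="at least 2"):
        ebayes_moderate(fit)


def test_trigamma_inverse_inverts_trigamma():
    for x in [0.01, 0.5, 3.0, 120.0]:
        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(x, rel=1e-8)


# ---------------------------------------------------------------- BH


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.04], [0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.03, 0.01], [0.03, 0.02]),
    ],
)
def test_bh_step_down_minimum_hand_examples(p, expected):
    np.testing.assert_allclose(bh_adjust(np.array(p)), expected)


def test_bh_matches_statsmodels_and_preserves_decision_order():
    rng = np.random.default_rng(10)
    p = rng.beta(0.4, 3.0, 500)
    q = bh_adjust(p)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, q_ref, atol=1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


# ---------------------------------------------------------------- calls, MDS


def test_dhmc_call_threshold_is_strict():
    table = pd.DataFrame(
        {"logFC": [1.0, -2.0, 0.5], "t": 0.0, "p": 0.0, "q": [0.049, 0.05, 0.051]},
        index=pd.RangeIndex(3),
    )
    from rrhp.diffhmc import ModeratedResult

    calls = call_dhmc(ModeratedResult(1.0, 1.0, table), q_max=0.05)
    assert list(calls.index) == [0]
    assert (calls["direction"] == "up").all()


def test_duplicated_samples_have_zero_mds_distance():
    rng = np.random.default_rng(11)
    y = pd.DataFrame(
        np.column_stack([rng.normal(size=100)] * 2 + [rng.normal(size=100)]),
        columns=["a", "b", "c"],
    )
    coords = mds_coordinates(y, top_sites=50)
    assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-6)
    assert not np.allclose(coords.loc["a"], coords.loc["c"], atol=1e-3)


def test_mds_separates_planted_groups():
    rng = np.random.default_rng(12)
    base = rng.normal(5, 1, (400, 1))
    y = np.tile(base, (1, 10)) + rng.normal(0, 0.1, (400, 10))
    y[:80, :5] += 2.0  # shared group effect in the first five samples
    frame = pd.DataFrame(y, columns=[f"s{i}" for i in range(10)])
    coords = mds_coordinates(frame, top_sites=100)
    dim1 = coords["dim1"].to_numpy()
    gap = abs(dim1[:5].mean() - dim1[5:].mean())
    spread = max(dim1[:5].std(), dim1[5:].std())
    assert gap > 3 * spread


# ---------------------------------------------------------------- limma oracle


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_full_path_matches_limma_reference(tmp_path):
    """voom -> lmFit -> eBayes -> BH agrees with the R reference end to end."""
    matrix = nb_matrix(13, n_sites=80)
    moderated, _, _ = differential_analysis(matrix)
    counts_path = tmp_path / "counts.tsv"
    matrix.counts.reset_index(drop=True).to_csv(counts_path, sep="\t", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        counts <- as.matrix(read.delim(commandArgs(TRUE)[1]))
        group <- factor(c(rep("large",5), rep("small",5)), levels=c("small","large"))
        design <- model.matrix(~group)
        fit <- eBayes(lmFit(voom(counts, design), design))
        tt <- topTable(fit, coef=2, number=Inf, sort.by="none")
        out <- data.frame(logFC=tt$logFC, t=tt$t, p=tt$P.Value, q=tt$adj.P.Val,
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, commandArgs(TRUE)[2], sep="\\t", row.names=FALSE, quote=FALSE)
        """
    )
    out_path = tmp_path / "r.tsv"
    subprocess.run(
        ["Rscript", str(script), str(counts_path), str(out_path)],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(out_path, sep="\t")
    np.testing.assert_allclose(moderated.table["logFC"], ref["logFC"], atol=1e-8)
    np.testing.assert_allclose(moderated.table["t"], ref["t"], atol=1e-6)
    np.testing.assert_allclose(moderated.table["q"], ref["q"], atol=1e-6)
    assert moderated.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert moderated.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
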