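"""REML engine: oracle equivalence, invariances, heteroscedastic recovery."""

import numpy as np
import pandas as pd
import pytest

from genebankqc import (DegreesOfFreedomError, EstimabilityError, FitSpec,
                        InsufficientDataError, VarianceParams,
                        fit_mixed_model, reml_criterion)
from genebankqc.simulate import SimulationConfig, simulate_dataset

from conftest import balanced_anova_components


def _noiseless_records():
    # effects sum to zero, total variance < 1 so the variance floor stays tiny
    g = np.array([-0.02, -0.01, 0.0, 0.01, 0.02])
    a = np.array([-0.3, -0.1, 0.1, 0.3])
    y = 10.0 + g[:, None] + a[None, :]
    return pd.DataFrame({
        "accession_id": np.repeat(list("ABCDE"), 4),
        "year": np.tile(np.arange(1990, 1994), 5),
        "value": y.ravel(),
    }), g, a


@pytest.mark.parametrize("roles", [("random", "fixed"), ("fixed", "random"),
                                   ("random", "random")])
def test_noiseless_grid_recovered_exactly(roles):
    """A noise-free additive grid is reproduced to numerical accuracy."""
    records, g, a = _noiseless_records()
    fit = fit_mixed_model(records, FitSpec(*roles, heteroscedastic=True))
    assert fit.sigma2_e_by_year.max() <= 1e-8
    assert np.abs(fit.residuals).max() < 1e-6
    # effect contrasts are parameterization-free
    est_g = fit.accession_effects.to_numpy()
    est_a = fit.year_effects.to_numpy()
    assert np.abs((est_g - est_g.mean()) - g).max() < 1e-6
    assert np.abs((est_a - est_a.mean()) - a).max() < 1e-6


def test_balanced_grid_matches_anova_closed_form(balanced_grid):
    """Both-random REML on a complete balanced grid equals the
    expected-mean-squares estimators (non-negative case)."""
    records, y = balanced_grid
    s2g, s2y, s2e = balanced_anova_components(y)
    fit = fit_mixed_model(records, FitSpec("random", "random",
                                           heteroscedastic=False))
    assert fit.converged
    assert fit.sigma2_g == pytest.approx(s2g, abs=1e-5)
    assert fit.sigma2_y == pytest.approx(s2y, abs=1e-5)
    assert fit.sigma2_e_by_year.iloc[0] == pytest.approx(s2e, abs=1e-5)


def test_heteroscedastic_two_year_variances_recovered():
    """Two years with error SDs 1 and 5 get separate variance estimates."""
    rng = np.random.default_rng(0)
    n_per = 200
    acc = [f"A{i:03d}" for i in range(n_per)]
    records = pd.DataFrame({
        "accession_id": acc * 2,
        "year": [2001] * n_per + [2002] * n_per,
        "value": np.concatenate([rng.normal(100, 1.0, n_per),
                                 rng.normal(100, 5.0, n_per)]),
    })
    fit = fit_mixed_model(records, FitSpec("random", "fixed",
                                           heteroscedastic=True))
    assert fit.sigma2_e_by_year[2001] == pytest.approx(1.0, rel=0.25)
    assert fit.sigma2_e_by_year[2002] == pytest.approx(25.0, rel=0.25)


def test_loglik_ascent_and_convergence(small_dataset):
    """The EM iterate sequence of the restricted loglik never decreases."""
    fit = fit_mixed_model(small_dataset.records,
                          FitSpec("random", "random", heteroscedastic=True))
    assert fit.converged
    diffs = np.diff(fit.loglik_trace)
    assert np.all(diffs >= -1e-6 * (np.abs(fit.loglik_trace[:-1]) + 1))


def test_criterion_maximal_at_fit_optimum(balanced_grid):
    """reml_criterion at the fitted solution beats +/-20% perturbations."""
    records, _ = balanced_grid
    spec = FitSpec("random", "random", heteroscedastic=False)
    fit = fit_mixed_model(records, spec)
    base = VarianceParams(sigma2_e_by_year=float(fit.sigma2_e_by_year.iloc[0]),
                          sigma2_g=fit.sigma2_g, sigma2_y=fit.sigma2_y)
    best = reml_criterion(records, base, spec)
    assert best == pytest.approx(fit.reml_loglik, abs=1e-6)
    for factor in (0.8, 1.2):
        perturbed = VarianceParams(
            sigma2_e_by_year=float(fit.sigma2_e_by_year.iloc[0]) * factor,
            sigma2_g=fit.sigma2_g * factor, sigma2_y=fit.sigma2_y * factor)
        assert reml_criterion(records, perturbed, spec) <= best + 1e-9


def test_criterion_translation_invariant(small_dataset):
    """Adding a constant to y shifts the criterion identically for any
    two parameter vectors (REML profiles the fixed effects out)."""
    records = small_dataset.records
    spec = FitSpec("random", "fixed", heteroscedastic=False)
    p1 = VarianceParams(sigma2_e_by_year=9.0, sigma2_g=15.0)
    p2 = VarianceParams(sigma2_e_by_year=13.0, sigma2_g=4.0)
    shifted = records.assign(value=records["value"] + 137.0)
    d_orig = (reml_criterion(records, p1, spec)
              - reml_criterion(records, p2, spec))
    d_shift = (reml_criterion(shifted, p1, spec)
               - reml_criterion(shifted, p2, spec))
    assert d_shift == pytest.approx(d_orig, abs=1e-8)


def _dense_reml_loglik(records, s2e_per_record, s2g=None, s2y=None,
                       n_fixed_cols=None):
    """Textbook REML loglik from explicit dense V and X (tiny n only)."""
    y = records["value"].to_numpy(float)
    n = len(y)
    acc = pd.Categorical(records["accession_id"],
                         categories=sorted(records["accession_id"].unique()))
    yr = pd.Categorical(records["year"],
                        categories=sorted(records["year"].unique()))
    Zg = np.eye(len(acc.categories))[acc.codes]
    Zy = np.eye(len(yr.categories))[yr.codes]
    V = np.diag(np.asarray(s2e_per_record, float))
    cols = []
    if s2g is None:
        cols.append(Zg)         # accessions fixed
    else:
        V = V + s2g * Zg @ Zg.T
    if s2y is None:
        cols.append(Zy)         # years fixed
    else:
        V = V + s2y * Zy @ Zy.T
    if not cols:
        cols.append(np.ones((n, 1)))
    X = np.column_stack(cols)   # full column rank in every config used here
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                   + y @ P @ y + (n - X.shape[1]) * np.log(2 * np.pi))


def test_single_year_reduces_to_one_factor_model():
    """With one year and years fixed the criterion equals the restricted
    loglik of the one-way (accession) model computed densely."""
    rng = np.random.default_rng(5)
    q, r = 6, 4
    records = pd.DataFrame({
        "accession_id": np.repeat([f"A{i}" for i in range(q)], r),
        "year": 2000,
        "value": rng.normal(20, 2, q * r),
    })
    s2g, s2e = 4.0, 2.5
    got = reml_criterion(records,
                         VarianceParams(sigma2_e_by_year=s2e, sigma2_g=s2g),
                         FitSpec("random", "fixed", heteroscedastic=False))
    expected = _dense_reml_loglik(records, np.full(q * r, s2e), s2g=s2g)
    assert got == pytest.approx(expected, abs=1e-8)


def test_criterion_matches_dense_oracle_all_configs():
    """Absorbed/Schur criterion equals the dense REML formula for every
    role configuration on a small non-orthogonal design."""
    data = simulate_dataset(SimulationConfig(
        n_accessions=12, n_years=5, obs_per_accession=3, seed=1))
    records = data.records
    s2e_year = {yr: 5.0 + i for i, yr in
                enumerate(sorted(records["year"].unique()))}
    s2e_rec = records["year"].map(s2e_year).to_numpy(float)
    configs = [
        (dict(sigma2_g=8.0), FitSpec("random", "fixed")),
        (dict(sigma2_y=40.0), FitSpec("fixed", "random")),
        (dict(sigma2_g=8.0, sigma2_y=40.0), FitSpec("random", "random")),
    ]
    for extra, spec in configs:
        spec.heteroscedastic = True
        spec.min_records_per_year_variance = 1
        got = reml_criterion(records,
                             VarianceParams(sigma2_e_by_year=s2e_year, **extra),
                             spec)
        expected = _dense_reml_loglik(records, s2e_rec,
                                      s2g=extra.get("sigma2_g"),
                                      s2y=extra.get("sigma2_y"))
        assert got == pytest.approx(expected, abs=1e-8)


def test_scaling_equivariance(small_dataset):
    """y -> k*y scales variances by k^2 and effects by k."""
    records = small_dataset.records
    spec = FitSpec("random", "random", heteroscedastic=True)
    fit1 = fit_mixed_model(records, spec)
    k = 3.0
    fit2 = fit_mixed_model(records.assign(value=records["value"] * k), spec)
    assert fit2.sigma2_g == pytest.approx(k**2 * fit1.sigma2_g, rel=1e-3)
    assert fit2.sigma2_y == pytest.approx(k**2 * fit1.sigma2_y, rel=1e-3)
    np.testing.assert_allclose(fit2.sigma2_e_by_year,
                               k**2 * fit1.sigma2_e_by_year, rtol=1e-3)
    np.testing.assert_allclose(fit2.accession_effects,
                               k * fit1.accession_effects, atol=1e-3)


def test_gradient_matches_dense_oracle():
    """Analytic log-variance gradient used by the polish step equals the
    dense-matrix score -0.5 [tr(P V_k) - y' P V_k P y] on a small design."""
    from genebankqc.mixed_model import _Design, _solve

    data = simulate_dataset(SimulationConfig(
        n_accessions=12, n_years=5, obs_per_accession=3, seed=1))
    records = data.records
    spec = FitSpec("random", "random", heteroscedastic=True,
                   min_records_per_year_variance=1)
    design = _Design(records, spec)
    theta = np.linspace(5.0, 15.0, design.n_groups + 2)
    theta[-2:] = [8.0, 40.0]
    state = _solve(design, theta)

    y = design.y
    n = design.n
    Zg = np.eye(design.q)[design.acc_idx]
    Zy = np.eye(design.m)[design.year_idx]
    X = np.ones((n, 1))
    s2e = theta[:design.n_groups][design.group_idx]
    V = theta[-2] * Zg @ Zg.T + theta[-1] * Zy @ Zy.T + np.diag(s2e)
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
    dense = []
    for k in range(design.n_groups):
        Vk = np.diag((design.group_idx == k).astype(float))
        dense.append(-0.5 * (np.trace(P @ Vk) - y @ P @ Vk @ P @ y) * theta[k])
    for Z, t in ((Zg, theta[-2]), (Zy, theta[-1])):
        ZZ = Z @ Z.T
        dense.append(-0.5 * (np.trace(P @ ZZ) - y @ P @ ZZ @ P @ y) * t)
    np.testing.assert_allclose(state.grad, dense, rtol=1e-8, atol=1e-10)


def test_residuals_centred_within_years(small_dataset):
    """With a year effect in the model, per-year residual means vanish."""
    fit = fit_mixed_model(small_dataset.records,
                          FitSpec("fixed", "random", heteroscedastic=True))
    resid = fit.residuals
    years = small_dataset.records["year"]
    sd = resid.std()
    # random year effects are shrunken, so means are near but not exactly 0
    assert np.abs(resid.groupby(years.to_numpy()).mean()).max() < 0.05 * sd


def test_error_contracts():
    one_acc = pd.DataFrame({"accession_id": ["A"] * 3,
                            "year": [1, 2, 3], "value": [1.0, 2.0, 3.0]})
    with pytest.raises(InsufficientDataError):
        fit_mixed_model(one_acc, FitSpec())
    # disconnected two-island design with both factors fixed
    records = pd.DataFrame({
        "accession_id": ["A", "A", "B", "C", "C", "D"],
        "year": [1, 2, 1, 3, 4, 4],
        "value": [1.0, 2, 3, 4, 5, 6],
    })
    with pytest.raises(EstimabilityError):
        fit_mixed_model(records, FitSpec("fixed", "fixed",
                                         heteroscedastic=True))
    few = pd.DataFrame({"accession_id": ["A", "B"], "year": [1, 2],
                        "value": [1.0, 2.0]})
    with pytest.raises(DegreesOfFreedomError):
        fit_mixed_model(few, FitSpec("fixed", "random"))


def test_small_years_share_pooled_variance():
    """Years under the minimum record count share one pooled sigma2_e."""
    cfg = SimulationConfig(n_accessions=40, n_years=8, obs_per_accession=4,
                           seed=3)
    records = simulate_dataset(cfg).records
    # cut two years down to 2 records each
    for year, keep in ((1986, 2), (1987, 2)):
        idx = records.index[records["year"] == year]
        records = records.drop(idx[keep:])
    fit = fit_mixed_model(records, FitSpec("random", "fixed",
                                           heteroscedastic=True,
                                           min_records_per_year_variance=5))
    s2 = fit.sigma2_e_by_year
    assert s2[1986] == s2[1987]          # pooled group
    big_years = [y for y in s2.index if y not in (1986, 1987)]
    assert s2[big_years].nunique() == len(big_years)
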