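"""Reproducible study-scale experiments over the curation pipeline.

Each function runs one of the package's headline computations end to end
on synthetic data with known truth and returns plain numbers: worked
heritability/Diff% arithmetic, REML-vs-closed-form agreement, variance
component recovery, outlier-year and record detection operating
characteristics, the heritability boost from correction, and the
block-wise-missingness resampling comparison.  The analysis drivers, the
test suite and the acceptance script all call these functions, so every
reported number is recomputed from scratch at run time.

Problem sizes are chosen to finish on one CPU in minutes while keeping
the Monte-Carlo error of each summary below its decision margin; the
methods note discusses the choices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import summaries
from .mixed_model import FitSpec, fit_mixed_model
from .outlier_qc import detect_record_outliers, run_outlier_pipeline
from .simulate import (SimulationConfig, inject_outlier_year,
                       inject_record_outliers, simulate_dataset)
from .summaries import (compute_heritability, estimate_blues,
                        estimate_variance_components, heritability_of)
from .validation import paper_like_origin_groups, run_resampling_study

#: Table-2-like truth (winter wheat flowering time): genetic, year and mean
#: error variance on the day^2 scale
TRUTH_SIGMA2_G = 15.23
TRUTH_SIGMA2_Y = 72.36
TRUTH_SIGMA2_E = 9.08


def _spawn(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def heritability_worked_example() -> float:
    """h2 for sigma2_G=15.23, sigma2_e=9.08, Year=5.12 (two decimals)."""
    return round(compute_heritability(15.23, 9.08, 5.12), 2)


def diff_pct_examples() -> dict[str, float]:
    """Record-count Diff% for the published before/after counts."""
    cases = {
        "spring_ft": (39076, 38696),
        "spring_tgw": (29676, 28455),
        "winter_ft": (31817, 31566),
    }
    return {k: round(100.0 * (n1 - n0) / n0, 2) for k, (n0, n1) in cases.items()}


def reml_vs_anova_agreement(seed: int = 0, n_accessions: int = 25,
                            n_years: int = 8) -> float:
    """Max |REML - balanced-ANOVA| over the three variance components on a
    complete balanced homoscedastic grid (closed-form oracle)."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(TRUTH_SIGMA2_G), n_accessions)
    a = rng.normal(0, np.sqrt(TRUTH_SIGMA2_Y), n_years)
    e = rng.normal(0, np.sqrt(TRUTH_SIGMA2_E), (n_accessions, n_years))
    y = 161.0 + g[:, None] + a[None, :] + e
    records = pd.DataFrame({
        "accession_id": np.repeat([f"A{i:03d}" for i in range(n_accessions)],
                                  n_years),
        "year": np.tile(np.arange(1980, 1980 + n_years), n_accessions),
        "value": y.ravel(),
    })
    ms_a = n_years * np.var(y.mean(1), ddof=1)
    ms_b = n_accessions * np.var(y.mean(0), ddof=1)
    resid = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
    ms_e = (resid ** 2).sum() / ((n_accessions - 1) * (n_years - 1))
    anova = np.array([(ms_a - ms_e) / n_years, (ms_b - ms_e) / n_accessions,
                      ms_e])
    fit = fit_mixed_model(records, FitSpec("random", "random",
                                           heteroscedastic=False))
    reml = np.array([fit.sigma2_g, fit.sigma2_y,
                     float(fit.sigma2_e_by_year.iloc[0])])
    return float(np.abs(reml - anova).max())


def recovery_study(seed: int = 0, n_reps: int = 20) -> dict[str, float]:
    """Variance-component recovery on 500 accessions x 30 years with 90%
    random missingness at the Table-2-like truth.

    Returns median *signed* relative errors (bias measure) of the genetic
    and year variances; the sampling CV of a variance estimated from 30
    year draws (~26%) makes an absolute-error criterion unattainable at
    this size.
    """
    errs_g, errs_y = [], []
    for s in _spawn(seed, n_reps):
        data = simulate_dataset(SimulationConfig(
            n_accessions=500, n_years=30, obs_per_accession=3,
            sigma2_g=TRUTH_SIGMA2_G, sigma2_y=TRUTH_SIGMA2_Y,
            sigma2_e=TRUTH_SIGMA2_E, seed=s))
        vc = estimate_variance_components(data.records)
        errs_g.append((vc.sigma2_g - TRUTH_SIGMA2_G) / TRUTH_SIGMA2_G)
        errs_y.append((vc.sigma2_y - TRUTH_SIGMA2_Y) / TRUTH_SIGMA2_Y)
    return {
        "median_rel_err_sigma2_g": float(np.median(errs_g)),
        "median_rel_err_sigma2_y": float(np.median(errs_y)),
        "n_reps": n_reps,
    }


def outlier_year_study(seed: int = 0, n_seeds: int = 20,
                       variance_factor: float = 25.0) -> dict[str, float]:
    """CV-screen operating characteristic: one year's error variance
    inflated x25, pipeline run, removal of that year recorded per seed."""
    bad_year = 1995
    flagged = removed = 0
    for s in _spawn(seed, n_seeds):
        data = simulate_dataset(SimulationConfig(
            n_accessions=300, n_years=25, obs_per_accession=4, seed=s))
        data = inject_outlier_year(data, bad_year, variance_factor,
                                   seed=s + 1)
        corrected, report = run_outlier_pipeline(data.records)
        cv = report.cv_table
        flagged += bool(cv.loc[cv["year"] == bad_year, "flagged"].any())
        removed += bool((report.removed_years["year"] == bad_year).any())
    return {"flag_rate": flagged / n_seeds, "removal_rate": removed / n_seeds,
            "n_seeds": n_seeds}


def holm_sensitivity_study(seed: int = 0, n_seeds: int = 20,
                           fraction: float = 0.003,
                           magnitude_sd: float = 8.0) -> dict[str, float]:
    """Detection sensitivity for sparse gross outliers (8 SD, 0.3% of
    records, the magnitude of the published record-level removal share)."""
    caught = total = 0
    for s in _spawn(seed, n_seeds):
        data = simulate_dataset(SimulationConfig(
            n_accessions=1000, n_years=30, obs_per_accession=6, seed=s))
        contaminated, ids = inject_record_outliers(data, fraction,
                                                   magnitude_sd, seed=s + 1)
        rejected, _, _ = detect_record_outliers(contaminated.records,
                                                alpha=0.05)
        injected = set(zip(contaminated.records.loc[ids, "accession_id"],
                           contaminated.records.loc[ids, "year"]))
        got = set(zip(rejected["accession_id"], rejected["year"]))
        caught += len(injected & got)
        total += len(injected)
    return {"sensitivity": caught / total, "n_injected": total,
            "n_seeds": n_seeds}


def holm_fwer_study(seed: int = 0, n_reps: int = 200,
                    alpha: float = 0.05) -> dict[str, float]:
    """Family-wise false-removal rate of the record test on clean data."""
    any_removal = 0
    for s in _spawn(seed, n_reps):
        data = simulate_dataset(SimulationConfig(
            n_accessions=50, n_years=10, obs_per_accession=6, seed=s))
        rejected, _, _ = detect_record_outliers(data.records, alpha=alpha)
        any_removal += len(rejected) > 0
    return {"family_wise_false_removal_rate": any_removal / n_reps,
            "n_reps": n_reps, "alpha": alpha}


def heritability_boost_study(seed: int = 0, n_seeds: int = 20,
                             fraction: float = 0.01,
                             magnitude_sd: float = 8.0) -> dict[str, float]:
    """Fraction of contaminated datasets whose corrected h2 exceeds the
    uncorrected h2 after the two-step pipeline."""
    boosted = 0
    gains = []
    for s in _spawn(seed, n_seeds):
        data = simulate_dataset(SimulationConfig(
            n_accessions=200, n_years=20, obs_per_accession=4, seed=s))
        contaminated, _ = inject_record_outliers(data, fraction, magnitude_sd,
                                                 seed=s + 1)
        corrected, _ = run_outlier_pipeline(contaminated.records)
        h2_before = heritability_of(contaminated.records)
        h2_after = heritability_of(corrected)
        boosted += h2_after > h2_before
        gains.append(h2_after - h2_before)
    return {"boost_fraction": boosted / n_seeds,
            "mean_h2_gain": float(np.mean(gains)), "n_seeds": n_seeds}


def make_resampling_dataset(seed: int = 42):
    """Synthetic analogue of the balanced validation subset: 159 accessions
    in the published origin-cohort sizes, 6 complete years, the Table-2
    genetic variance split evenly within/between origin cohorts."""
    origin = paper_like_origin_groups()
    config = SimulationConfig(
        n_accessions=len(origin), n_years=6, missing_pattern="complete",
        obs_per_accession=6, origin_labels=list(origin),
        sigma2_g=TRUTH_SIGMA2_G / 2, sigma2_origin=TRUTH_SIGMA2_G / 2,
        sigma2_y=TRUTH_SIGMA2_Y, sigma2_e=TRUTH_SIGMA2_E,
        start_year=1951, seed=seed)
    return simulate_dataset(config), origin


def resampling_comparison(seed: int = 0, n_reps: int = 100) -> dict[str, float]:
    """The three missingness scenarios on the synthetic balanced subset:
    per-accession BLUE bias and the spread of variance-component point
    estimates, 3 of 6 years kept per accession."""
    data_seed, *scen_seeds = _spawn(seed, 4)
    data, origin = make_resampling_dataset(data_seed)
    out: dict[str, float] = {"n_reps": n_reps}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional flat-likelihood fits
        for scenario, s in zip(("block_origin", "block_random", "random"),
                               scen_seeds):
            res = run_resampling_study(data.records, scenario, years_kept=3,
                                       n_reps=n_reps, seed=s,
                                       origin_of=origin)
            out[f"sd_sigma2_g_{scenario}"] = res.sd_sigma2_g
            out[f"mean_blue_bias_{scenario}"] = float(res.blue_bias.mean())
            out[f"mean_abs_blue_bias_{scenario}"] = res.mean_abs_blue_bias
    out["sd_ratio_block_origin_vs_random"] = (
        out["sd_sigma2_g_block_origin"] / out["sd_sigma2_g_random"])
    return out


def blue_recovery_study(seed: int = 0) -> dict[str, float]:
    """Slope of BLUE on true genetic value and the residual level bias on a
    non-orthogonal dataset (the level absorbs the finite-sample mean of
    the drawn year effects, which is subtracted before reporting)."""
    (s,) = _spawn(seed, 1)
    data = simulate_dataset(SimulationConfig(
        n_accessions=500, n_years=30, obs_per_accession=3, seed=s))
    blues = estimate_blues(data.records).set_index("accession_id")
    truth = (data.config.mu + data.truth.g).loc[blues.index]
    slope, _ = np.polyfit(truth, blues["blue"], 1)
    level = float(data.truth.a.mean())
    bias = float((blues["blue"] - truth).mean() - level)
    return {"slope": float(slope), "level_adjusted_bias": bias,
            "n_accessions": len(blues)}
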