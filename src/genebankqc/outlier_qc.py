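"""Two-step outlier correction for historical regeneration phenotypes.

Step 1 screens whole trait-years: the model is fitted with accessions
random and years fixed (heteroscedastic), each year's coefficient of
variation

    CV_j = sqrt(sigma2_e*_j) / YE_j

is computed from the year-specific error variance and the estimated year
marginal mean, and years whose CV deviates more than three standard
deviations from the average CV become candidates.  A candidate is removed
only after adjudication: removal must improve the heritability by more
than ``delta_h2``, or a strong weather anomaly (|z| >= 4, the evidence
standard used for the 1961 thousand-grain-weight year) must corroborate it
while the heritability does not get worse.

Step 2 removes individual records: the model is refitted on the
step-1-corrected data with accessions fixed and years random, internally
studentized residuals are tested two-sided against a t reference, and the
Bonferroni-Holm step-down procedure controls the family-wise error rate.
Both steps run once, in that order (no iterative re-fitting by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, ValidationError
from .mixed_model import FitResult, FitSpec, fit_mixed_model
from . import summaries
from . import validation as _validation

__all__ = ["CVTable", "OutlierReport", "compute_year_cv",
           "flag_candidate_years", "adjudicate_year",
           "detect_record_outliers", "run_outlier_pipeline"]

#: family-wise level of the Holm test (the analysis default)
DEFAULT_ALPHA = 0.05
#: minimum heritability gain that justifies dropping a year; heritabilities
#: are reported at 2 decimals, smaller changes are invisible at that scale
DEFAULT_DELTA_H2 = 0.005
#: |z| needed for weather corroboration of a candidate year
STRONG_ANOMALY_Z = 4.0

CVTable = pd.DataFrame  # columns: year, YE, sigma2_e_star, cv, flagged


@dataclass
class OutlierReport:
    """What the two-step correction removed, and why."""

    removed_years: pd.DataFrame     # year, reason, h2_with, h2_without
    removed_records: pd.DataFrame   # accession_id, year, value, t, holm_p
    untestable: pd.DataFrame        # leverage-one records excluded from testing
    cv_table: CVTable
    summary: dict = field(default_factory=dict)


def compute_year_cv(records: pd.DataFrame,
                    spec: FitSpec | None = None) -> CVTable:
    """Per-year CV from the accessions-random / years-fixed fit.

    Years whose estimated marginal mean is not positive get an undefined
    (NaN) CV with a warning - a coefficient of variation is meaningless
    around a non-positive mean.
    """
    if records["year"].nunique() < 2:
        raise InsufficientDataError("need >= 2 years with records for the CV screen")
    spec = spec or FitSpec(accession_role="random", year_role="fixed",
                           heteroscedastic=True)
    fit = fit_mixed_model(records, spec)
    ye = fit.year_effects
    s2e = fit.sigma2_e_by_year
    cv = np.sqrt(s2e) / ye
    bad = ye <= 0
    if bad.any():
        warnings.warn(
            f"non-positive year mean for year(s) {list(ye.index[bad])}; "
            "CV undefined there", stacklevel=2)
        cv[bad] = np.nan
    return pd.DataFrame({
        "year": ye.index.to_numpy(),
        "YE": ye.to_numpy(float),
        "sigma2_e_star": s2e.to_numpy(float),
        "cv": cv.to_numpy(float),
        "flagged": False,
    })


def flag_candidate_years(cv_table: CVTable) -> CVTable:
    """Flag years whose CV deviates > 3 SD from the average CV.

    Mean and SD are computed over all defined CV values, candidates
    included (no leave-one-out).  With fewer than 3 defined values the SD
    rule cannot run and nothing is flagged by it; undefined CVs are always
    flagged for inspection.
    """
    out = cv_table.copy()
    cv = out["cv"].to_numpy(float)
    defined = np.isfinite(cv)
    flags = ~defined  # undefined CV -> inspect
    if defined.sum() >= 3:
        mean = cv[defined].mean()
        sd = cv[defined].std(ddof=1)
        if sd > 0:
            flags |= defined & (np.abs(cv - mean) > 3.0 * sd)
    out["flagged"] = flags
    return out


def adjudicate_year(records: pd.DataFrame, candidate_year: int,
                    weather: pd.DataFrame | None = None,
                    delta_h2: float = DEFAULT_DELTA_H2) -> tuple[str, dict]:
    """Decide whether a CV-flagged year is really an outlier year.

    Removal requires either a heritability gain larger than ``delta_h2``,
    or a strong corroborating weather anomaly (|z| >= 4 in that year) with
    the heritability not decreasing.  Returns ``(decision, evidence)``
    with decision in {"remove", "keep"}; the evidence dict carries both
    heritability estimates and the anomaly list so a curator can override.
    """
    years = records["year"].to_numpy()
    if candidate_year not in set(years.tolist()):
        raise ValidationError(f"candidate year {candidate_year} absent from records")

    h2_with = summaries.heritability_of(records)
    without = records.loc[years != candidate_year]
    h2_without = summaries.heritability_of(without)

    anomalies_df = pd.DataFrame()
    no_data = True
    strong = False
    if weather is not None and len(weather):
        z = _validation.standardize_weather(weather)
        report = _validation.weather_anomaly_report(z, candidate_year,
                                                    min_abs_z=STRONG_ANOMALY_Z)
        anomalies_df = report.entries
        no_data = report.no_data
        strong = len(anomalies_df) > 0

    gain = h2_without - h2_with
    if not math.isinf(delta_h2) and gain > delta_h2:
        decision, reason = "remove", "cv+heritability"
    elif strong and gain >= 0:
        decision, reason = "remove", "cv+weather"
    else:
        decision, reason = "keep", ""
    evidence = {
        "h2_with": h2_with,
        "h2_without": h2_without,
        "h2_gain": gain,
        "weather_anomalies": anomalies_df,
        "weather_no_data": no_data,
        "reason": reason,
    }
    return decision, evidence


def detect_record_outliers(records: pd.DataFrame,
                           alpha: float = DEFAULT_ALPHA,
                           spec: FitSpec | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, FitResult]:
    """Studentized-residual record test with Bonferroni-Holm control.

    Fits the model with accessions fixed and years random on the (step-1
    corrected) records, studentizes each residual internally with its
    exact leverage from the absorbed normal equations,

        t_r = e_r / (sigma_e_j * sqrt(1 - h_r)),

    and tests two-sided against a t distribution on the effective residual
    degrees of freedom of the record's variance group.  Records with
    leverage ~1 (an accession's only record in the fit) have residual
    identically zero and are excluded from testing, listed separately.

    Returns ``(rejected, untestable, fit)``: the Holm-rejected records to
    remove in a single pass, the untestable ones, and the underlying fit.
    """
    spec = spec or FitSpec(accession_role="fixed", year_role="random",
                           heteroscedastic=True)
    fit = fit_mixed_model(records, spec)

    h = fit.leverages.to_numpy(float)
    resid = fit.residuals.to_numpy(float)
    years = records["year"].to_numpy()
    s2e = fit.sigma2_e_by_year.loc[years].to_numpy(float)
    df = fit.effective_df_by_year.loc[years].to_numpy(float)

    testable = h < 1.0 - 1e-8
    untestable = records.loc[~testable, ["accession_id", "year", "value"]].copy()

    t = np.full(len(records), np.nan)
    t[testable] = resid[testable] / np.sqrt(s2e[testable] *
                                            (1.0 - h[testable]))
    dof = np.maximum(df, 1.0)
    p = np.full(len(records), np.nan)
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), dof[testable])

    report = records.loc[testable, ["accession_id", "year", "value"]].copy()
    report["studentized_residual"] = t[testable]
    report["p_value"] = p[testable]
    if len(report):
        reject, holm_p, _, _ = multipletests(report["p_value"].to_numpy(),
                                             alpha=alpha, method="holm")
    else:
        reject = np.zeros(0, bool)
        holm_p = np.zeros(0)
    report["holm_p"] = holm_p
    rejected = (report.loc[reject]
                .sort_values(["year", "accession_id"], kind="stable"))
    return rejected, untestable, fit


def run_outlier_pipeline(records: pd.DataFrame,
                         weather: pd.DataFrame | None = None,
                         alpha: float = DEFAULT_ALPHA,
                         delta_h2: float = DEFAULT_DELTA_H2,
                         ) -> tuple[pd.DataFrame, OutlierReport]:
    """Full two-step correction: CV year screen, then Holm record test.

    Returns the corrected records plus a report separating the two removal
    routes with per-step counts and percentages.  Heritability never
    decreases through an adjudicated year removal (by construction of the
    adjudication rule; asserted here on every run).
    """
    n0 = len(records)
    removed_year_rows = []

    if records["year"].nunique() >= 2:
        cv_table = flag_candidate_years(compute_year_cv(records))
    else:
        cv_table = pd.DataFrame(
            columns=["year", "YE", "sigma2_e_star", "cv", "flagged"])

    step1 = records
    for year in cv_table.loc[cv_table["flagged"], "year"]:
        decision, evidence = adjudicate_year(step1, year, weather, delta_h2)
        if decision == "remove":
            assert evidence["h2_without"] >= evidence["h2_with"] - 1e-12
            step1 = step1.loc[step1["year"] != year]
            removed_year_rows.append({
                "year": year,
                "reason": evidence["reason"],
                "h2_with": evidence["h2_with"],
                "h2_without": evidence["h2_without"],
            })
    removed_years = pd.DataFrame(
        removed_year_rows,
        columns=["year", "reason", "h2_with", "h2_without"])
    n_year_removed = n0 - len(step1)

    rejected, untestable, _fit = detect_record_outliers(step1, alpha)
    corrected = step1.drop(index=rejected.index)

    summary = {
        "n_input": n0,
        "n_removed_year_step": int(n_year_removed),
        "n_removed_record_step": int(len(rejected)),
        "n_corrected": int(len(corrected)),
        "pct_removed_year_step": 100.0 * n_year_removed / n0 if n0 else 0.0,
        "pct_removed_record_step": 100.0 * len(rejected) / n0 if n0 else 0.0,
        "pct_removed_total": (100.0 * (n0 - len(corrected)) / n0) if n0 else 0.0,
    }
    report = OutlierReport(removed_years, rejected.reset_index(drop=True),
                           untestable.reset_index(drop=True), cv_table, summary)
    assert summary["n_input"] == (summary["n_corrected"]
                                  + summary["n_removed_record_step"]
                                  + summary["n_removed_year_step"])
    return corrected, report
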