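"""Deliverables: BLUEs, variance components, heritability, descriptives.

BLUEs are adjusted accession means on the trait scale from the
accessions-fixed / years-random fit.  Variance components come from the
both-random fit; the heritability of the non-orthogonal data is

    h2 = sigma2_G / (sigma2_G + sigma2_e / Year)

with sigma2_e the (unweighted) average error variance across regeneration
years and Year the average number of distinct years each accession was
evaluated.  Descriptive summaries report counts before/after correction
with the relative difference Diff% = 100 (corrected - original)/original.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .mixed_model import FitSpec, fit_mixed_model

__all__ = ["BLUETable", "HeritabilityResult", "estimate_blues",
           "estimate_variance_components", "compute_heritability",
           "heritability_of", "descriptive_summary", "correlate_traits"]

logger = logging.getLogger(__name__)

BLUETable = pd.DataFrame  # columns: accession_id, blue, se, n_years


@dataclass
class HeritabilityResult:
    """Variance components and the repeatability they imply."""

    sigma2_g: float
    sigma2_y: float
    sigma2_e: float      # average error variance across years
    mean_years: float    # average evaluations per accession
    h2: float | None = None


def estimate_blues(records: pd.DataFrame,
                   spec: FitSpec | None = None) -> BLUETable:
    """Adjusted accession means (BLUEs) with standard errors.

    One row per accession with at least one surviving record, sorted by
    accession_id.  Standard errors come from the inverse of the absorbed
    coefficient matrix at the converged variances.
    """
    spec = spec or FitSpec(accession_role="fixed", year_role="random",
                           heteroscedastic=True)
    fit = fit_mixed_model(records, spec)
    n_years = records.groupby("accession_id")["year"].nunique()
    table = pd.DataFrame({
        "accession_id": fit.accession_effects.index,
        "blue": fit.accession_effects.to_numpy(float),
        "se": fit.standard_errors["accession"].to_numpy(float),
        "n_years": n_years.loc[fit.accession_effects.index].to_numpy(int),
    }).sort_values("accession_id", kind="stable").reset_index(drop=True)
    return table


def mean_evaluation_years(records: pd.DataFrame, harmonic: bool = False
                          ) -> float:
    """Average number of distinct observation years per accession.

    Arithmetic by default (the convention behind the reported 5.12 years
    for winter-wheat flowering time); a harmonic-mean variant is available
    because parts of the breeding literature use it.
    """
    counts = records.groupby("accession_id")["year"].nunique().to_numpy(float)
    if harmonic:
        return float(len(counts) / np.sum(1.0 / counts))
    return float(counts.mean())


def estimate_variance_components(records: pd.DataFrame,
                                 spec: FitSpec | None = None,
                                 harmonic_mean_years: bool = False
                                 ) -> HeritabilityResult:
    """Variance components from the both-random heteroscedastic fit.

    ``sigma2_e`` is the unweighted arithmetic mean of the per-year error
    variances; ``h2`` is left unset (see :func:`compute_heritability`).
    """
    if records["accession_id"].nunique() < 2 or records["year"].nunique() < 2:
        raise InsufficientDataError("need >= 2 accessions and >= 2 years")
    spec = spec or FitSpec(accession_role="random", year_role="random",
                           heteroscedastic=True)
    fit = fit_mixed_model(records, spec)
    return HeritabilityResult(
        sigma2_g=float(fit.sigma2_g),
        sigma2_y=float(fit.sigma2_y),
        sigma2_e=float(fit.sigma2_e_by_year.mean()),
        mean_years=mean_evaluation_years(records, harmonic_mean_years),
    )


def compute_heritability(sigma2_g: float, sigma2_e: float,
                         mean_years: float) -> float:
    """h2 = sigma2_G / (sigma2_G + sigma2_e / Year); rounding only at print."""
    if mean_years <= 0:
        raise ValueError("mean_years must be > 0")
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValueError("variances must be >= 0")
    if sigma2_g == 0 and sigma2_e == 0:
        raise ValueError("sigma2_g and sigma2_e cannot both be 0")
    return sigma2_g / (sigma2_g + sigma2_e / mean_years)


def fill_heritability(vc: HeritabilityResult) -> HeritabilityResult:
    return replace(vc, h2=compute_heritability(vc.sigma2_g, vc.sigma2_e,
                                               vc.mean_years))


def heritability_of(records: pd.DataFrame) -> float:
    """Convenience: both-random fit, then the heritability in one call."""
    vc = estimate_variance_components(records)
    return compute_heritability(vc.sigma2_g, vc.sigma2_e, vc.mean_years)


def descriptive_summary(original: pd.DataFrame, corrected: pd.DataFrame,
                        blues: BLUETable | None = None) -> pd.DataFrame:
    """Counts before/after correction with Diff% per quantity.

    Rows: records, accessions, years; optionally the BLUE dispersion
    (mean, min, max) of the corrected data, in trait units.
    """
    def counts(df: pd.DataFrame) -> dict:
        return {
            "records": len(df),
            "accessions": df["accession_id"].nunique(),
            "years": df["year"].nunique(),
        }

    c0, c1 = counts(original), counts(corrected)
    rows = []
    for key in c0:
        diff = 100.0 * (c1[key] - c0[key]) / c0[key] if c0[key] else np.nan
        rows.append({"quantity": key, "original": c0[key],
                     "corrected": c1[key], "diff_pct": diff})
    out = pd.DataFrame(rows)
    if blues is not None and len(blues):
        disp = blues["blue"]
        for name, val in (("blue_mean", disp.mean()), ("blue_min", disp.min()),
                          ("blue_max", disp.max())):
            rows.append({"quantity": name, "original": np.nan,
                         "corrected": val, "diff_pct": np.nan})
        out = pd.DataFrame(rows)
    return out


def correlate_traits(tables: dict[str, BLUETable]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations of accession BLUEs between traits.

    Returns (r, p) matrices over accessions shared pairwise; two-sided
    p-values from the t transform of r.  Fewer than 3 shared accessions
    for a pair is an error.
    """
    names = list(tables)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names,
                     columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            merged = tables[a].merge(tables[b], on="accession_id",
                                     suffixes=("_a", "_b"))
            if len(merged) < 3:
                raise InsufficientDataError(
                    f"traits {a} and {b} share only {len(merged)} accessions")
            res = stats.pearsonr(merged["blue_a"], merged["blue_b"])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
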