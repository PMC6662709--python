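"""Technical-validation computations.

Weather standardization: each monthly value is expressed as a z-score
against its month-and-parameter climatology across all available years
(the year under inspection included), so an anomalous April rainfall reads
directly as "x standard deviations above the April average".  Anomaly
reports for a given year feed the adjudication of CV-flagged years.

Temporal trends (e.g. flowering progressively earlier, spring warming) are
ordinary least-squares slopes per calendar year.

The resampling study quantifies what block-wise missingness does to the
precision of estimated statistics: starting from a complete accession x
year grid, three missingness scenarios are drawn repeatedly (year subsets
shared within origin cohorts / shared within randomly composed blocks /
independent per accession), the model is refitted each time, and the
spread of the variance-component point estimates plus the BLUE bias are
summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (ConfigurationError, InsufficientDataError,
                         ValidationError)
from . import summaries

__all__ = ["WeatherAnomalyReport", "TrendResult", "ResamplingResult",
           "standardize_weather", "weather_anomaly_report", "linear_trend",
           "run_resampling_study", "compare_with_orthogonal"]

logger = logging.getLogger(__name__)

#: |z| labels: >= 4 is the evidence standard used for outlier-year
#: corroboration, >= 2 is worth a look
SEVERITY_STRONG = 4.0
SEVERITY_NOTABLE = 2.0


@dataclass
class WeatherAnomalyReport:
    year: int
    min_abs_z: float
    entries: pd.DataFrame      # month, parameter, value, z, severity
    no_data: bool = False


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p_value: float
    r_value: float
    n: int


@dataclass
class ResamplingResult:
    scenario: str
    n_reps: int
    years_kept: int
    blue_bias: pd.Series       # per-accession mean(resampled - full BLUE)
    sd_sigma2_g: float
    sd_sigma2_y: float
    sd_sigma2_e: float
    sigma2_g_estimates: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mean_abs_blue_bias(self) -> float:
        return float(np.abs(self.blue_bias).mean())


def _severity(z: np.ndarray) -> np.ndarray:
    out = np.full(z.shape, "", dtype=object)
    out[np.abs(z) >= SEVERITY_NOTABLE] = "notable"
    out[np.abs(z) >= SEVERITY_STRONG] = "strong"
    return out


def standardize_weather(weather: pd.DataFrame,
                        leave_one_out: bool = False,
                        min_years: int = 3) -> pd.DataFrame:
    """z-scores of monthly weather values against their climatology.

    The climatology (mean, SD across years) is computed per (month,
    parameter) over all years with data, including the year being
    standardized; a leave-one-out variant is available.  Cells whose
    climatology rests on fewer than ``min_years`` years, or whose SD is
    zero, yield no entries (logged).
    """
    if not len(weather):
        return pd.DataFrame(columns=["year", "month", "parameter", "value",
                                     "z", "severity"])
    df = weather.copy()
    grp = df.groupby(["month", "parameter"])["value"]
    n = grp.transform("count")
    mean = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=1))
    if leave_one_out:
        # mean/sd of the other years: downdate the pooled moments
        loo_mean = (n * mean - df["value"]) / (n - 1)
        ss = (n - 1) * sd**2
        loo_ss = ss - (df["value"] - loo_mean) * (df["value"] - mean)
        sd = np.sqrt(loo_ss / (n - 2))
        mean = loo_mean
        n = n - 1
    ok = (n >= min_years) & (sd > 0)
    dropped = (~ok).sum()
    if dropped:
        logger.info("standardize_weather: %d cells without a defined "
                    "climatology dropped", int(dropped))
    out = df.loc[ok].copy()
    out["z"] = (out["value"] - mean[ok]) / sd[ok]
    out["severity"] = _severity(out["z"].to_numpy(float))
    return out.sort_values(["year", "month", "parameter"],
                           kind="stable").reset_index(drop=True)


def weather_anomaly_report(anomalies: pd.DataFrame, year: int,
                           min_abs_z: float = SEVERITY_NOTABLE
                           ) -> WeatherAnomalyReport:
    """Anomalies of one year with |z| >= min_abs_z, month-then-parameter.

    A year entirely absent from the standardized table yields an empty
    report flagged ``no_data`` (the case of candidate years before the
    weather series begins).
    """
    if "z" not in anomalies.columns:
        raise ValidationError("expected a standardized weather table "
                              "(standardize_weather output)")
    of_year = anomalies.loc[anomalies["year"] == year]
    if not len(of_year):
        return WeatherAnomalyReport(year, min_abs_z,
                                    of_year.reset_index(drop=True),
                                    no_data=True)
    hits = of_year.loc[np.abs(of_year["z"]) >= min_abs_z]
    hits = hits.sort_values(["month", "parameter"],
                            kind="stable").reset_index(drop=True)
    return WeatherAnomalyReport(year, min_abs_z, hits, no_data=False)


def linear_trend(x, y) -> TrendResult:
    """OLS slope per calendar year with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 points for a trend")
    if np.unique(x).size < 2:
        raise ValidationError("degenerate x: fewer than 2 distinct values")
    res = stats.linregress(x, y)
    return TrendResult(float(res.slope), float(res.intercept),
                       float(res.pvalue), float(res.rvalue), len(x))


# ---------------------------------------------------------------------------
# resampling study

RESAMPLING_SCENARIOS = ("block_origin", "block_random", "random")


def _scenario_mask(scenario: str, acc_ids: np.ndarray, years: np.ndarray,
                   origin_of: pd.Series | None, years_kept: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """(accession_id, year) pairs kept in one replicate."""
    m = len(years)
    k = years_kept
    if scenario == "random":
        kept = {a: rng.choice(years, size=k, replace=False) for a in acc_ids}
    elif scenario in ("block_origin", "block_random"):
        if scenario == "block_origin":
            if origin_of is None:
                raise ConfigurationError(
                    "block_origin scenario requires origin labels")
            labels = origin_of.loc[acc_ids].to_numpy()
        else:
            # same block sizes as the origin cohorts (or 8 equal blocks),
            # but randomly composed
            if origin_of is not None:
                sizes = origin_of.loc[acc_ids].value_counts().to_numpy()
            else:
                n_blocks = min(8, len(acc_ids))
                base = len(acc_ids) // n_blocks
                sizes = np.full(n_blocks, base)
                sizes[: len(acc_ids) - base * n_blocks] += 1
            perm = rng.permutation(len(acc_ids))
            labels = np.empty(len(acc_ids), dtype=object)
            start = 0
            for b, size in enumerate(sizes):
                labels[perm[start:start + size]] = f"block{b}"
                start += size
        kept = {}
        for lab in pd.unique(labels):
            subset = rng.choice(years, size=k, replace=False)
            for a in acc_ids[labels == lab]:
                kept[a] = subset
    else:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    rows = [(a, int(y)) for a in acc_ids for y in kept[a]]
    return pd.DataFrame(rows, columns=["accession_id", "year"])


def run_resampling_study(balanced_records: pd.DataFrame, scenario: str,
                         years_kept: int, n_reps: int = 100, seed: int = 0,
                         origin_of: pd.Series | None = None
                         ) -> ResamplingResult:
    """Precision of BLUEs and variance components under a missingness scenario.

    ``balanced_records`` must be a complete accession x year grid (every
    accession observed in every year).  Per replicate a missingness mask
    keeping ``years_kept`` years per accession is drawn according to the
    scenario, the model is refitted, and BLUEs plus variance components
    recorded.  Deterministic for a given seed.
    """
    if scenario not in RESAMPLING_SCENARIOS:
        raise ConfigurationError(
            f"scenario must be one of {RESAMPLING_SCENARIOS}")
    acc_ids = np.sort(balanced_records["accession_id"].unique())
    years = np.sort(balanced_records["year"].unique())
    cells = balanced_records.groupby(["accession_id", "year"]).size()
    if len(cells) != len(acc_ids) * len(years):
        raise ValidationError("balanced_records is not a complete grid")
    if not 1 <= years_kept <= len(years):
        raise ConfigurationError("years_kept must be in [1, n_years]")

    full_blues = summaries.estimate_blues(balanced_records)
    full_blue = full_blues.set_index("accession_id")["blue"]

    rng = np.random.default_rng(seed)
    bias_sum = pd.Series(0.0, index=full_blue.index)
    comps = {"g": [], "y": [], "e": []}
    for _ in range(n_reps):
        mask = _scenario_mask(scenario, acc_ids, years, origin_of,
                              years_kept, rng)
        sub = balanced_records.merge(mask, on=["accession_id", "year"])
        blues = summaries.estimate_blues(sub).set_index("accession_id")["blue"]
        bias_sum += blues.reindex(full_blue.index) - full_blue
        vc = summaries.estimate_variance_components(sub)
        comps["g"].append(vc.sigma2_g)
        comps["y"].append(vc.sigma2_y)
        comps["e"].append(vc.sigma2_e)

    sd = {k: float(np.std(v, ddof=1)) if n_reps > 1 else 0.0
          for k, v in comps.items()}
    return ResamplingResult(
        scenario=scenario,
        n_reps=n_reps,
        years_kept=years_kept,
        blue_bias=bias_sum / n_reps,
        sd_sigma2_g=sd["g"],
        sd_sigma2_y=sd["y"],
        sd_sigma2_e=sd["e"],
        sigma2_g_estimates=np.asarray(comps["g"]),
    )


def paper_like_origin_groups() -> pd.Series:
    """Origin labels for the synthetic analogue of the validation subset.

    Cohort sizes follow the published subset: Germany 51, USA 42, Sweden
    27, Greece 15, then France/Afghanistan/Albania/Great Britain 6 each
    (159 accessions; the source's own total differs by one from its
    counts).  Indexed by generated accession_id.
    """
    sizes = {"Germany": 51, "United States": 42, "Sweden": 27, "Greece": 15,
             "France": 6, "Afghanistan": 6, "Albania": 6, "Great Britain": 6}
    labels = np.repeat(list(sizes), list(sizes.values()))
    ids = [f"ACC{i + 1:04d}" for i in range(len(labels))]
    return pd.Series(labels, index=ids, name="origin")


def compare_with_orthogonal(historical: pd.DataFrame, trial: pd.DataFrame
                            ) -> dict:
    """Mean shift and Pearson r between historical and trial BLUEs.

    Both inputs are BLUE tables; the statistics run over accessions present
    in both.  The shift is mean(trial - historical) in trait units.
    """
    merged = historical.merge(trial, on="accession_id",
                              suffixes=("_hist", "_trial"))
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} shared accessions; need >= 3")
    diff = merged["blue_trial"] - merged["blue_hist"]
    res = stats.pearsonr(merged["blue_hist"], merged["blue_trial"])
    return {
        "n_shared": int(len(merged)),
        "mean_shift": float(diff.mean()),
        "pearson_r": float(res.statistic),
        "p_value": float(res.pvalue),
    }
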