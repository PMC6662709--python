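"""Synthetic non-orthogonal regeneration datasets with known ground truth.

The generator emulates the statistical structure of historical genebank
phenotypes: an additive two-way model

    y_ij = mu + g_i + a_j + e_ij

with accession effects g_i ~ N(0, sigma2_g), year effects a_j ~ N(0,
sigma2_y) and year-specific error variances sigma2_e_j, observed on a
heavily incomplete accession x year grid (~90% of cells empty in the real
collections).  Missingness can be completely random per accession, or
block-wise: accessions that entered the collection together (same origin
cohort) were regenerated in the same years, confounding origin with year.

Defaults follow the winter-wheat flowering-time magnitudes of the study
conditions: mu = 161 days (10 June), sigma2_g = 15.23, sigma2_y = 72.36,
mean error variance 9.08, ~3 observation years per accession out of 30.

Contamination helpers inject gross record outliers (shifted by a multiple
of the year's residual SD) and inflated-variance outlier years, mirroring
the data-quality failures the curation pipeline is built to catch.

No attempt is made to emulate genetic relatedness, trait correlations or
weather-phenotype coupling; those are out of scope for the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

MISSING_PATTERNS = ("complete", "random", "block_origin", "block_random")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic phenotype generator (see module docstring)."""

    n_accessions: int = 500
    n_years: int = 30
    mu: float = 161.0
    sigma2_g: float = 15.23
    #: between-origin-cohort genetic variance (collection hotspots differ in
    #: their breeding pools); added on top of sigma2_g, needs origin_labels
    sigma2_origin: float = 0.0
    sigma2_y: float = 72.36
    #: mean of the per-year error variances when no explicit vector is given
    sigma2_e: float = 9.08
    #: SD of log error variances (log-normal spread across years); 0 = equal
    sigma2_e_log_sd: float = 0.3
    #: explicit per-year error variances; overrides the log-normal rule
    error_variance_per_year: Sequence[float] | None = None
    missing_pattern: str = "random"
    obs_per_accession: int = 3
    #: origin label per accession (block_origin pattern and resampling study)
    origin_labels: Sequence[str] | None = None
    #: number of contiguous accession blocks for block_random
    n_blocks: int = 8
    trait: str = "FT"
    start_year: int = 1986
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1 or self.n_years < 1:
            raise ConfigurationError("need at least one accession and one year")
        for name in ("sigma2_g", "sigma2_origin", "sigma2_y", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sigma2_origin > 0 and self.origin_labels is None:
            raise ConfigurationError("sigma2_origin > 0 requires origin_labels")
        if self.missing_pattern not in MISSING_PATTERNS:
            raise ConfigurationError(
                f"missing_pattern {self.missing_pattern!r} not one of "
                f"{MISSING_PATTERNS}"
            )
        if self.missing_pattern != "complete":
            if not 1 <= self.obs_per_accession <= self.n_years:
                raise ConfigurationError(
                    "obs_per_accession must be in [1, n_years]"
                )
        if self.missing_pattern == "block_origin" and self.origin_labels is None:
            raise ConfigurationError(
                "block_origin pattern requires origin_labels"
            )
        if self.origin_labels is not None and \
                len(self.origin_labels) != self.n_accessions:
            raise ConfigurationError(
                "origin_labels length must equal n_accessions"
            )
        if self.error_variance_per_year is not None:
            ev = np.asarray(self.error_variance_per_year, float)
            if len(ev) != self.n_years or (ev <= 0).any():
                raise ConfigurationError(
                    "error_variance_per_year needs n_years positive entries"
                )


@dataclass
class Truth:
    """Ground-truth components behind a simulated dataset."""

    mu: float
    g: pd.Series               # accession effects, indexed by accession_id
    a: pd.Series               # year effects, indexed by year
    sigma2_e_by_year: pd.Series
    errors: pd.Series          # per-record residual draw, aligned to records


@dataclass
class SimulatedDataset:
    records: pd.DataFrame      # accession_id, year, trait, value, replicate_index
    truth: Truth
    config: SimulationConfig

    def reconstruct(self) -> np.ndarray:
        """mu + g_i + a_j + e for every record; equals ``value`` exactly."""
        t = self.truth
        return (t.mu
                + t.g.loc[self.records["accession_id"]].to_numpy()
                + t.a.loc[self.records["year"]].to_numpy()
                + t.errors.to_numpy())


def _accession_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"ACC{i + 1:0{width}d}" for i in range(n)])


def _year_subsets(config: SimulationConfig, rng: np.random.Generator
                  ) -> list[np.ndarray]:
    """Observed year indices per accession, by missingness pattern."""
    q, m, k = config.n_accessions, config.n_years, config.obs_per_accession
    if config.missing_pattern == "complete":
        return [np.arange(m)] * q
    if config.missing_pattern == "random":
        return [np.sort(rng.choice(m, size=k, replace=False)) for _ in range(q)]
    if config.missing_pattern == "block_origin":
        # Each origin cohort farms one contiguous run of years, runs staggered
        # across cohorts: emulates intake cohorts regenerated together.
        labels = np.asarray(config.origin_labels)
        groups = list(dict.fromkeys(labels))  # stable order of appearance
        n_starts = m - k + 1
        starts = {
            g: (round(i * (n_starts - 1) / max(1, len(groups) - 1))
                if len(groups) > 1 else 0)
            for i, g in enumerate(groups)
        }
        return [np.arange(starts[lab], starts[lab] + k) for lab in labels]
    if config.missing_pattern == "block_random":
        # Contiguous accession blocks (ignoring origin) share staggered runs.
        n_blocks = min(config.n_blocks, q)
        block_of = np.minimum((np.arange(q) * n_blocks) // q, n_blocks - 1)
        n_starts = m - k + 1
        starts = [
            round(b * (n_starts - 1) / max(1, n_blocks - 1)) if n_blocks > 1 else 0
            for b in range(n_blocks)
        ]
        return [np.arange(starts[b], starts[b] + k) for b in block_of]
    raise ConfigurationError(config.missing_pattern)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under the additive model with known truth.

    Deterministic for a given config+seed.  Sub-streams for effects,
    errors and missingness are derived from the seed independently, so a
    later contamination step never perturbs the base draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_g, rng_a, rng_e, rng_miss = (np.random.default_rng(s)
                                     for s in ss.spawn(4))

    q, m = config.n_accessions, config.n_years
    acc_ids = _accession_ids(q)
    years = np.arange(config.start_year, config.start_year + m)

    g_values = rng_g.normal(0.0, np.sqrt(config.sigma2_g), q)
    if config.sigma2_origin > 0:
        labels = np.asarray(config.origin_labels)
        groups = list(dict.fromkeys(labels))
        shift = dict(zip(groups, rng_g.normal(
            0.0, np.sqrt(config.sigma2_origin), len(groups))))
        g_values = g_values + np.array([shift[lab] for lab in labels])
    # truth.g carries the total genetic value (cohort shift included)
    g = pd.Series(g_values, index=acc_ids)
    a = pd.Series(rng_a.normal(0.0, np.sqrt(config.sigma2_y), m), index=years)

    if config.error_variance_per_year is not None:
        s2e = np.asarray(config.error_variance_per_year, float)
    elif config.sigma2_e == 0:
        s2e = np.zeros(m)
    elif config.sigma2_e_log_sd > 0:
        s = config.sigma2_e_log_sd
        # log-normal with mean equal to sigma2_e
        s2e = np.exp(rng_e.normal(np.log(config.sigma2_e) - s**2 / 2, s, m))
    else:
        s2e = np.full(m, config.sigma2_e)
    sigma2_e_by_year = pd.Series(s2e, index=years)

    subsets = _year_subsets(config, rng_miss)
    acc_idx = np.repeat(np.arange(q), [len(s) for s in subsets])
    year_idx = np.concatenate(subsets) if subsets else np.array([], int)

    errors = rng_e.normal(0.0, np.sqrt(s2e[year_idx]))
    values = (config.mu + g.to_numpy()[acc_idx] + a.to_numpy()[year_idx]
              + errors)
    records = pd.DataFrame(
        {
            "accession_id": acc_ids[acc_idx],
            "year": years[year_idx],
            "trait": config.trait,
            "value": values,
            "replicate_index": 1,
        }
    )
    truth = Truth(config.mu, g, a, sigma2_e_by_year,
                  pd.Series(errors, index=records.index))
    return SimulatedDataset(records, truth, config)


def inject_record_outliers(data: SimulatedDataset, fraction: float,
                           magnitude_sd: float, seed: int
                           ) -> tuple[SimulatedDataset, list]:
    """Shift round(fraction * n) records by +/- magnitude_sd x sigma_e_j.

    The sign is random and symmetric.  Returns the contaminated dataset and
    the list of contaminated record indices (into ``records``), for scoring
    detection sensitivity and specificity.
    """
    if not 0 <= fraction < 1:
        raise ConfigurationError("fraction must be in [0, 1)")
    if magnitude_sd <= 0:
        raise ConfigurationError("magnitude_sd must be > 0")
    rng = np.random.default_rng(seed)
    n = len(data.records)
    n_out = int(round(fraction * n))
    records = data.records.copy()
    errors = data.truth.errors.copy()
    if n_out == 0:
        return SimulatedDataset(records, replace(data.truth, errors=errors),
                                data.config), []
    idx = np.sort(rng.choice(n, size=n_out, replace=False))
    signs = rng.choice([-1.0, 1.0], size=n_out)
    sd_j = np.sqrt(
        data.truth.sigma2_e_by_year.loc[records["year"].iloc[idx]].to_numpy()
    )
    shift = signs * magnitude_sd * sd_j
    records.iloc[idx, records.columns.get_loc("value")] += shift
    errors.iloc[idx] += shift
    truth = replace(data.truth, errors=errors)
    return SimulatedDataset(records, truth, data.config), list(records.index[idx])


def inject_outlier_year(data: SimulatedDataset, year: int,
                        variance_factor: float, seed: int) -> SimulatedDataset:
    """Re-draw one year's residuals with the variance inflated.

    Emulates a year in which field conditions ruined measurement quality:
    the year keeps its true year effect but its error variance is
    multiplied by ``variance_factor`` (> 1).  All other years' records are
    untouched; the truth table is updated accordingly.
    """
    if variance_factor <= 1:
        raise ConfigurationError("variance_factor must be > 1")
    years = data.records["year"].to_numpy()
    if year not in set(years.tolist()):
        raise ValidationError(f"year {year} has no records")
    rng = np.random.default_rng(seed)
    mask = years == year
    old_var = float(data.truth.sigma2_e_by_year.loc[year])
    new_var = old_var * variance_factor
    new_err = rng.normal(0.0, np.sqrt(new_var), int(mask.sum()))

    records = data.records.copy()
    errors = data.truth.errors.copy()
    t = data.truth
    base = (t.mu + t.g.loc[records.loc[mask, "accession_id"]].to_numpy()
            + t.a.loc[year])
    records.loc[mask, "value"] = base + new_err
    errors.loc[mask] = new_err
    s2e = t.sigma2_e_by_year.copy()
    s2e.loc[year] = new_var
    truth = Truth(t.mu, t.g, t.a, s2e, errors)
    return SimulatedDataset(records, truth, data.config)


def default_climatology() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly means/SDs of the five weather parameters.

    A temperate central-European station (continental lowland): cold
    winters, ~490 mm annual rain, high winter air humidity.  SDs are
    across-year SDs of monthly values.
    """
    months = np.arange(1, 13)
    t_avg = np.array([-1.0, 0.2, 4.0, 8.5, 13.5, 16.5,
                      18.5, 18.0, 14.0, 9.0, 4.0, 0.5])
    spread = np.array([6.5, 7.0, 7.5, 8.5, 9.5, 10.0,
                       10.5, 10.5, 9.0, 7.5, 6.0, 5.5])
    means = pd.DataFrame(
        {
            "T.avg": t_avg,
            "T.min": t_avg - spread / 2,
            "T.max": t_avg + spread / 2,
            "Rain": np.array([35, 30, 35, 40, 50, 60, 55, 50, 40, 35, 40, 45],
                             float),
            "Moisture": np.array([86, 83, 79, 73, 70, 70, 71, 73, 79, 83, 86, 87],
                                 float),
        },
        index=pd.Index(months, name="month"),
    )
    sds = pd.DataFrame(
        {
            "T.avg": np.full(12, 1.8),
            "T.min": np.full(12, 2.2),
            "T.max": np.full(12, 2.0),
            "Rain": means["Rain"].to_numpy() * 0.35,
            "Moisture": np.full(12, 3.0),
        },
        index=means.index,
    )
    return means, sds


def simulate_weather(n_years: int,
                     monthly_means: pd.DataFrame | None = None,
                     monthly_sds: pd.DataFrame | None = None,
                     anomalies: Sequence[tuple[int, int, str, float]] = (),
                     seed: int = 0,
                     start_year: int = 1986) -> pd.DataFrame:
    """Draw monthly weather series around a month-specific climatology.

    Values are N(mean_m, sd_m^2) per month m; each listed anomaly
    ``(year, month, parameter, z)`` then adds ``z * sd_m`` to its cell.
    Rain is clipped at 0 and Moisture to [0, 100] to keep physical bounds
    (clipping is negligible at the default climatology).  Deterministic per
    seed.  Returns a long DataFrame (year, month, parameter, value).
    """
    if monthly_means is None or monthly_sds is None:
        dm, ds = default_climatology()
        monthly_means = dm if monthly_means is None else monthly_means
        monthly_sds = ds if monthly_sds is None else monthly_sds
    params = list(monthly_means.columns)
    if set(monthly_means.index) < set(range(1, 13)) or \
            set(monthly_sds.index) < set(range(1, 13)):
        raise ConfigurationError("climatology tables must cover months 1-12")
    for year, month, param, _z in anomalies:
        if param not in params:
            raise ConfigurationError(f"anomaly references unknown parameter "
                                     f"{param!r}")
        if not 1 <= month <= 12:
            raise ConfigurationError(f"anomaly month {month} outside 1-12")

    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    rows = []
    for param in params:
        mean_m = monthly_means[param].reindex(range(1, 13)).to_numpy(float)
        sd_m = monthly_sds[param].reindex(range(1, 13)).to_numpy(float)
        draws = rng.normal(mean_m, sd_m, size=(n_years, 12))
        rows.append(pd.DataFrame({
            "year": np.repeat(years, 12),
            "month": np.tile(np.arange(1, 13), n_years),
            "parameter": param,
            "value": draws.ravel(),
        }))
    weather = pd.concat(rows, ignore_index=True)
    weather = weather.set_index(["year", "month", "parameter"]).sort_index()
    for year, month, param, z in anomalies:
        if (year, month, param) in weather.index:
            sd_m = float(monthly_sds.loc[month, param])
            weather.loc[(year, month, param), "value"] += z * sd_m
    weather = weather.reset_index()
    rain = weather["parameter"] == "Rain"
    weather.loc[rain, "value"] = weather.loc[rain, "value"].clip(lower=0.0)
    moist = weather["parameter"] == "Moisture"
    weather.loc[moist, "value"] = weather.loc[moist, "value"].clip(0.0, 100.0)
    return weather.sort_values(["year", "month", "parameter"],
                               kind="stable").reset_index(drop=True)


def make_study_table(dataset: SimulatedDataset) -> pd.DataFrame:
    """Accession metadata table for a simulated dataset (for I/O round-trips)."""
    records = dataset.records
    first_year = records.groupby("accession_id")["year"].min()
    acc = dataset.truth.g.index
    labels = dataset.config.origin_labels
    return pd.DataFrame(
        {
            "accession_id": acc,
            "accession_number": [f"TRI {i + 1}" for i in range(len(acc))],
            "organism": "Triticum aestivum L.",
            "sowing_date": None,
            "harvest_year": first_year.reindex(acc).astype("Int64").to_numpy(),
            "origin_country": (list(labels) if labels is not None
                               else "Unknown"),
            "origin_group": "",
        }
    )
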