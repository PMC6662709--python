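"""Synthetic-data generator: truth bookkeeping, moments, contamination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genebankqc import ConfigurationError, ValidationError
from genebankqc.simulate import (SimulationConfig, inject_outlier_year,
                                 inject_record_outliers, simulate_dataset,
                                 simulate_weather)


def test_zero_variance_complete_grid_is_constant():
    cfg = SimulationConfig(n_accessions=5, n_years=4, mu=10.0, sigma2_g=0,
                           sigma2_y=0, sigma2_e=0, sigma2_e_log_sd=0,
                           missing_pattern="complete", obs_per_accession=4)
    data = simulate_dataset(cfg)
    assert len(data.records) == 20
    assert np.all(data.records["value"] == 10.0)


def test_random_pattern_record_counts():
    cfg = SimulationConfig(n_accessions=40, n_years=6, obs_per_accession=3,
                           missing_pattern="random", seed=2)
    data = simulate_dataset(cfg)
    counts = data.records.groupby("accession_id").size()
    assert (counts == 3).all()


def test_truth_reconstruction_is_exact():
    cfg = SimulationConfig(n_accessions=30, n_years=10, obs_per_accession=4,
                           seed=9)
    data = simulate_dataset(cfg)
    np.testing.assert_array_equal(data.reconstruct(),
                                  data.records["value"].to_numpy())


def test_reproducibility_same_seed_same_bytes(tmp_path):
    from genebankqc import write_table
    cfg = SimulationConfig(n_accessions=25, n_years=8, seed=13,
                           obs_per_accession=3)
    for name in ("a", "b"):
        write_table(simulate_dataset(cfg).records, tmp_path / f"{name}.txt")
    assert (tmp_path / "a.txt").read_text() == (tmp_path / "b.txt").read_text()


def test_variance_decomposition_moments():
    """Sample variances of drawn g, a, e match the configured components
    within 3 standard errors of a variance estimate (chi-square theory)."""
    cfg = SimulationConfig(n_accessions=2000, n_years=30, mu=100.0,
                           sigma2_g=15.0, sigma2_y=70.0, sigma2_e=9.0,
                           sigma2_e_log_sd=0.0, missing_pattern="complete",
                           obs_per_accession=30, seed=17)
    data = simulate_dataset(cfg)
    checks = [
        (data.truth.g.var(ddof=1), 15.0, 2000),
        (data.truth.a.var(ddof=1), 70.0, 30),
        (data.truth.errors.var(ddof=1), 9.0, 60000),
    ]
    for sample_var, target, n in checks:
        se = target * np.sqrt(2.0 / (n - 1))
        assert abs(sample_var - target) < 3 * se


def test_block_origin_shares_year_subsets():
    labels = ["DE"] * 10 + ["SE"] * 10 + ["IR"] * 10
    cfg = SimulationConfig(n_accessions=30, n_years=12, obs_per_accession=4,
                           missing_pattern="block_origin",
                           origin_labels=labels, seed=5)
    data = simulate_dataset(cfg)
    years_of = data.records.groupby("accession_id")["year"].agg(
        lambda s: tuple(sorted(s)))
    acc = sorted(years_of.index)
    by_group = {lab: {years_of[a] for a, l in zip(acc, labels) if l == lab}
                for lab in ("DE", "SE", "IR")}
    for subsets in by_group.values():
        assert len(subsets) == 1       # shared within cohort
        (subset,) = subsets
        assert np.all(np.diff(subset) == 1)   # contiguous run
    assert len({s for ss in by_group.values() for s in ss}) > 1  # staggered


def test_origin_cohort_genetic_component():
    """With sigma2_origin > 0 accessions of the same cohort share a mean
    shift; total genetic variance approaches sigma2_g + sigma2_origin."""
    groups = [f"G{k}" for k in range(12)]
    labels = [g for g in groups for _ in range(100)]
    cfg = SimulationConfig(n_accessions=1200, n_years=4, obs_per_accession=2,
                           sigma2_g=6.0, sigma2_origin=8.0,
                           origin_labels=labels, seed=19)
    data = simulate_dataset(cfg)
    g = data.truth.g
    acc = g.index.to_numpy()
    by_group = g.groupby(pd.Series(labels, index=acc)).mean()
    assert by_group.std(ddof=1) > 1.0          # cohorts really differ
    assert by_group.std(ddof=1) < 6.0          # ... at the configured scale
    within = g - by_group.loc[labels].to_numpy()
    se = 6.0 * np.sqrt(2.0 / (len(g) - 1))
    assert abs(within.var(ddof=1) - 6.0) < 4 * se
    with pytest.raises(ConfigurationError):
        simulate_dataset(SimulationConfig(n_accessions=10, n_years=4,
                                          obs_per_accession=2,
                                          sigma2_origin=1.0))


def test_block_pattern_requires_labels():
    with pytest.raises(ConfigurationError):
        simulate_dataset(SimulationConfig(n_accessions=10, n_years=5,
                                          obs_per_accession=2,
                                          missing_pattern="block_origin"))


def test_random_pattern_year_inclusion_exchangeable():
    """Cell inclusion under the random pattern is uniform across years:
    a chi-square goodness-of-fit on pooled year totals is not rejected."""
    totals = np.zeros(6)
    for seed in range(30):
        cfg = SimulationConfig(n_accessions=50, n_years=6,
                               obs_per_accession=2, seed=seed)
        data = simulate_dataset(cfg)
        totals += data.records["year"].value_counts().reindex(
            range(1986, 1992), fill_value=0).to_numpy()
    stat, p = stats.chisquare(totals)
    assert p > 0.01


class TestRecordOutliers:
    def test_zero_fraction_is_identity(self):
        data = simulate_dataset(SimulationConfig(n_accessions=20, n_years=5,
                                                 obs_per_accession=3, seed=1))
        out, ids = inject_record_outliers(data, 0.0, 8.0, seed=2)
        assert ids == []
        pd.testing.assert_frame_equal(out.records, data.records)

    def test_single_cell_shift_arithmetic(self):
        data = simulate_dataset(SimulationConfig(n_accessions=20, n_years=5,
                                                 obs_per_accession=5, seed=1))
        n = len(data.records)
        out, ids = inject_record_outliers(data, 1.0 / n, 10.0, seed=3)
        assert len(ids) == 1
        diff = out.records["value"] - data.records["value"]
        changed = diff[diff != 0]
        assert list(changed.index) == ids
        year = data.records.loc[ids[0], "year"]
        sd = np.sqrt(data.truth.sigma2_e_by_year[year])
        assert abs(changed.iloc[0]) == pytest.approx(10.0 * sd)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_contamination_count(self, seed):
        data = simulate_dataset(SimulationConfig(n_accessions=50, n_years=8,
                                                 obs_per_accession=4, seed=4))
        out, ids = inject_record_outliers(data, 0.03, 6.0, seed=seed)
        assert len(ids) == round(0.03 * len(data.records))


class TestOutlierYear:
    def test_factor_must_exceed_one(self):
        data = simulate_dataset(SimulationConfig(n_accessions=10, n_years=4,
                                                 obs_per_accession=2, seed=1))
        with pytest.raises(ConfigurationError):
            inject_outlier_year(data, 1986, 1.0, seed=0)
        with pytest.raises(ValidationError):
            inject_outlier_year(data, 1900, 25.0, seed=0)

    def test_variance_inflation_and_locality(self):
        cfg = SimulationConfig(n_accessions=300, n_years=5,
                               obs_per_accession=5,
                               missing_pattern="complete", sigma2_e=9.0,
                               sigma2_e_log_sd=0.0, seed=6)
        data = simulate_dataset(cfg)
        out = inject_outlier_year(data, 1988, 25.0, seed=7)
        mask = out.records["year"] == 1988
        emp = out.truth.errors[mask.to_numpy()].var(ddof=1)
        n = int(mask.sum())
        se = 225.0 * np.sqrt(2.0 / (n - 1))
        assert abs(emp - 225.0) < 3 * se
        pd.testing.assert_frame_equal(out.records.loc[~mask],
                                      data.records.loc[~mask])
        assert out.truth.sigma2_e_by_year[1988] == pytest.approx(
            25.0 * data.truth.sigma2_e_by_year[1988])


class TestWeather:
    def test_zero_sd_reproduces_climatology(self):
        means = pd.DataFrame({"T.avg": np.linspace(0, 11, 12)},
                             index=pd.Index(range(1, 13), name="month"))
        sds = means * 0.0
        w = simulate_weather(2, means, sds, seed=1, start_year=2000)
        got = w.pivot_table(index="month", columns="year", values="value")
        for year in (2000, 2001):
            np.testing.assert_allclose(got[year], means["T.avg"])

    def test_anomaly_shift_arithmetic(self):
        means = pd.DataFrame({"Rain": np.full(12, 40.0)},
                             index=pd.Index(range(1, 13), name="month"))
        sds = pd.DataFrame({"Rain": np.full(12, 10.0)}, index=means.index)
        base = simulate_weather(3, means, sds, seed=2, start_year=2000)
        shifted = simulate_weather(3, means, sds,
                                   anomalies=[(2001, 4, "Rain", 4.0)],
                                   seed=2, start_year=2000)
        diff = shifted["value"] - base["value"]
        hit = (shifted["year"] == 2001) & (shifted["month"] == 4)
        assert np.allclose(diff[hit], 40.0)
        assert np.allclose(diff[~hit], 0.0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_weather(2, anomalies=[(2000, 4, "Snow", 1.0)],
                             start_year=2000)

    def test_monthly_sample_means_match_climatology(self):
        """Month-wise means over 200 years within 3 SE of the targets."""
        w = simulate_weather(200, seed=8, start_year=1800)
        t = w[w.parameter == "T.avg"]
        from genebankqc.simulate import default_climatology
        means, sds = default_climatology()
        got = t.groupby("month")["value"].mean()
        se = sds["T.avg"] / np.sqrt(200)
        assert (np.abs(got - means["T.avg"]) < 3 * se).all()
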