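#!/usr/bin/env python
"""Build the working synthetic collection for the downstream analyses.

Simulates a flowering-time-like historical dataset (300 accessions scored
in 4 of 25 regeneration years, additive accession and year effects,
year-specific error variances at the winter-wheat magnitudes), then
degrades it the way the real archive is degraded: one regeneration year
gets its error variance inflated 25-fold (a ruined field season) and 0.3%
of records become gross outliers at +/-10 residual SD.  A 63-year monthly
weather series is simulated alongside, with an extraordinary April
rainfall anomaly (+5 SD) placed in the bad year.

Writes the study/assay files, the contaminated records, the truth, and
the weather table under results/analysis/.
"""

import os

import pandas as pd

from genebankqc import write_isatab, write_table
from genebankqc.simulate import (SimulationConfig, inject_outlier_year,
                                 inject_record_outliers, make_study_table,
                                 simulate_dataset, simulate_weather)

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")
BAD_YEAR = 1995
SEED = 2024


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    config = SimulationConfig(n_accessions=300, n_years=25,
                              obs_per_accession=4, seed=SEED)
    clean = simulate_dataset(config)
    spoiled = inject_outlier_year(clean, BAD_YEAR, variance_factor=25.0,
                                  seed=SEED + 1)
    data, contaminated_ids = inject_record_outliers(spoiled, fraction=0.003,
                                                    magnitude_sd=10.0,
                                                    seed=SEED + 2)
    study_path, assay_path = write_isatab(
        data.records, make_study_table(data), OUT, stem="FT")
    write_table(data.records, os.path.join(OUT, "records.FT.txt"))
    truth = pd.DataFrame({"accession_id": data.truth.g.index,
                          "genetic_value": data.truth.g.to_numpy()})
    truth.to_csv(os.path.join(OUT, "truth.accessions.txt"), sep="\t",
                 index=False, lineterminator="\n")

    weather = simulate_weather(
        63, anomalies=[(BAD_YEAR, 4, "Rain", 5.0),
                       (BAD_YEAR, 4, "Moisture", 2.5)],
        seed=SEED + 3, start_year=1953)
    write_table(weather, os.path.join(OUT, "weather.txt"))

    print(f"simulated {len(data.records)} records for "
          f"{config.n_accessions} accessions in {config.n_years} years")
    print(f"injected outlier year {BAD_YEAR} (variance x25) and "
          f"{len(contaminated_ids)} gross record outliers (+/-10 SD)")
    print(f"weather: 63 years with April {BAD_YEAR} rainfall at +5 SD")
    print(f"outputs under {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
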