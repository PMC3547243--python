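"""Screen meteorological features against season characteristics.

Derives the decade/monthly predictor features (Temp_6, Temp_9,
Temp_M23, Temp_M4, Rain_12, Hum_4, Hum_10, Cloud_6) from the
synthetic met series and retains the Spearman correlations significant
at the 0.01 level on the training years (all but the last two).
"""

from pathlib import Path

import pandas as pd

from pollencast.io_core import read_met_csv, read_pollen_csv
from pollencast.met_features import DEFAULT_FEATURE_SPEC, feature_matrix
from pollencast.season_metrics import METHODS, season_table
from pollencast.stats_screen import screen

ROOT = Path(__file__).resolve().parents[1]
N_HOLDOUT = 2


def main() -> None:
    met = read_met_csv(ROOT / "results" / "synthetic" / "met.csv")
    pollen = read_pollen_csv(ROOT / "results" / "synthetic" / "pollen.csv")
    train_years = sorted(met)[:-N_HOLDOUT]

    features = feature_matrix(met, DEFAULT_FEATURE_SPEC)
    features.to_csv(ROOT / "results" / "feature_matrix.csv")
    seasons = season_table(pollen, METHODS["98/95"])
    chars = pd.DataFrame(
        {
            "SS": seasons["start"],
            "SE": seasons["end"],
            "PD": seasons["peak_day"],
            "PC": seasons["peak_concentration"],
            "SPI": seasons["spi"],
        }
    )
    chars.to_csv(ROOT / "results" / "characteristics.csv")

    out = screen(features.loc[train_years], chars.loc[train_years], alpha=0.01)
    out.to_csv(ROOT / "results" / "correlation_table.csv", index=False)
    print(
        f"{len(out)} of {out.attrs['n_tests']} correlations significant "
        f"at the 0.01 level (training years {train_years[0]}-{train_years[-1]}):"
    )
    print(out.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
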