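"""Generate the 20-year synthetic monitoring study.

Writes daily meteorological observations, daily birch pollen
concentrations and the truth sidecar (the generating season-start
linkage) to results/synthetic/.  Later scripts read these files the
same way they would read real station exports.
"""

from pathlib import Path

from pollencast.synthetic_data import GeneratorConfig, generate_study

SEED = 20
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    config = GeneratorConfig(n_years=20, first_year=1991, seed=SEED)
    met, pollen, truth = generate_study(config, out_dir=OUT, overwrite=True)
    print(f"wrote {config.n_years} years ({min(met)}-{max(met)}) to {OUT}")
    print(
        "generating linkage: start = "
        f"{config.start_intercept} {config.start_temp_coef:+}*Temp_6 "
        f"{config.start_hum_coef:+}*(Hum_10 - normal), noise SD "
        f"{config.start_noise_sd} days"
    )
    print(truth[["true_start", "spi_draw"]].describe().loc[["mean", "std", "min", "max"]])


if __name__ == "__main__":
    main()
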