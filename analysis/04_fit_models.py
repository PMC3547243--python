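"""Fit backward-stepwise forecast models for the season characteristics.

For each target (SS, SE, PD, PC): filter the candidate features for
mutual collinearity (|r| <= 0.7), then eliminate terms backwards at
alpha = 0.05, on the training years only.  Writes the model table and
prints the fitted equations with R-squared.
"""

from pathlib import Path

import pandas as pd

from pollencast.model_build import backward_stepwise, collinearity_filter

ROOT = Path(__file__).resolve().parents[1]
N_HOLDOUT = 2
TARGETS = ["SS", "SE", "PD", "PC"]


def main() -> None:
    features = pd.read_csv(ROOT / "results" / "feature_matrix.csv", index_col=0)
    chars = pd.read_csv(ROOT / "results" / "characteristics.csv", index_col=0)
    train = sorted(features.index)[:-N_HOLDOUT]

    rows = []
    for target in TARGETS:
        y = chars.loc[train, target].rename(target)
        kept = collinearity_filter(features.loc[train], y, threshold=0.7)
        model = backward_stepwise(features.loc[train, kept], y, alpha_remove=0.05)
        print(f"{model.equation()}   R2 = {model.r2:.3f}  (n = {model.n})")
        for name, coef, t, p in zip(
            model.terms, model.coefficients, model.t_values, model.p_values
        ):
            rows.append(
                {"target": target, "term": name, "coefficient": coef, "t": t, "p": p,
                 "intercept": model.intercept, "r2": model.r2, "n": model.n}
            )
    pd.DataFrame(rows).to_csv(ROOT / "results" / "model_table.csv", index=False)
    print(f"\nwrote {ROOT / 'results' / 'model_table.csv'}")


if __name__ == "__main__":
    main()
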