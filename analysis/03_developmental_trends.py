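#!/usr/bin/env python
"""Developmental-trend analysis: threshold ladders, predictor R², model choice.

Reads results/wi_table.csv and writes the age- and height-threshold trend
tables (trees below 1 m excluded from the age analysis to stay clear of the
soil-respiration layer), the per-predictor R² table and the AIC model
selection summary under results/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from ringwue import run_develop_trends

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    wi = pd.read_csv(ROOT / "wi_table.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_develop_trends(wi)

    out["age_trends"].to_csv(ROOT / "age_trends.csv", index=False, lineterminator="\n")
    out["height_trends"].to_csv(ROOT / "height_trends.csv", index=False, lineterminator="\n")
    r2 = pd.DataFrame(out["predictor_r2"]).T
    r2.to_csv(ROOT / "predictor_r2.csv", lineterminator="\n")

    sel = out["model_selection"]
    pd.DataFrame(
        [{"predictors": "+".join(c[0]) or "(intercept)", "aic": c[1], "r_squared": c[2]}
         for c in sel.candidates]
    ).to_csv(ROOT / "model_selection.csv", index=False, lineterminator="\n")

    full_age = out["age_trends"].iloc[0]
    full_h = out["height_trends"].iloc[0]
    print(f"age trend (full range, trees >= 1 m): {full_age['slope']:.1f} "
          f"ppm (100 yr)^-1 {full_age['stars']}")
    print(f"height trend (full range): {full_h['slope']:.1f} ppm (10 m)^-1 "
          f"{full_h['stars']}")
    print("per-predictor R^2: "
          + ", ".join(f"{k}={v['r_squared']:.2f}" for k, v in out["predictor_r2"].items()))
    print(f"most parsimonious model: {'+'.join(sel.selected)} "
          f"(R^2 = {sel.selected_r2:.2f})")


if __name__ == "__main__":
    main()
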