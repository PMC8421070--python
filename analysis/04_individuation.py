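#!/usr/bin/env python
"""Individuation models: can the PO model explain who deflects how much?

Reads the obstacle-cohort summaries, fits the one-parameter-plus-offset and
three-parameter-plus-offset individuation models, decomposes the explained
variance into partial R^2 per input variable (1-target safety margin,
2-target variability, 1-target variability), and writes per-variable
partial-residual tables for scatter plots.

Outputs: results/individuation_report_<variant>.json and
results/partial_residuals_<variant>_<variable>.csv.
"""

import pandas as pd

from common import CONFIGS, RESULTS, summaries_path

from reachplan.individuation import (VARIABLES, fit_three_param,
                                     partial_residual_data)
from reachplan.obstacle_models import frame_to_summaries
from reachplan.pipeline import cmd_individuation, write_report


def main() -> None:
    for variant in ("expt2a", "expt2b"):
        cohort = frame_to_summaries(pd.read_csv(summaries_path(variant)))
        rep = cmd_individuation(CONFIGS[variant], cohort=cohort)
        path = write_report(rep, RESULTS / f"individuation_report_{variant}.json")
        one, three = rep["one_param"], rep["three_param"]
        print(f"{variant} (n = {rep['n']}):")
        print(f"  one-param:  k = {one['k']:.2f}, R^2 = {one['r2']:.2f} "
              f"(F = {one['F']:.1f}, p = {one['p']:.2e})")
        print(f"  three-param: km = {three['km']:.2f}, k_sigma2 = {three['k2']:.2f}, "
              f"k_sigma1 = {three['k1']:.2f}, R^2 = {three['r2']:.2f}")
        parts = rep["partial_r2"]
        print("  partial R^2: " + ", ".join(
            f"{v} = {parts[v]['partial_r2']:.2f} (p = {parts[v]['p']:.1e})"
            for v in VARIABLES))
        full = fit_three_param(cohort)
        for v in VARIABLES:
            x, y = partial_residual_data(cohort, v, full=full)
            out = RESULTS / f"partial_residuals_{variant}_{v}.csv"
            pd.DataFrame({v: x, "mu2_partial_residual": y}).to_csv(out, index=False)
        print(f"  wrote {path} and partial-residual tables")


if __name__ == "__main__":
    main()
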