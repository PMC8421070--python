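#!/usr/bin/env python
"""Obstacle safety-margin models: baseline and refined MA vs. PO.

Reads the obstacle-cohort summary tables, evaluates the parameter-free
baseline models and the fitted one-parameter refinements, cross-validates
each refined model between the two obstacle variants, and writes
results/obstacle_report_<variant>.json.

Because both cohorts are generated under PO ground truth, the PO family
should dominate: small squared errors, a direction prediction index near
+1 in the pared-down variant, and a much smaller cross-validated MSE
increase than the MA family.
"""

import pandas as pd

from common import CONFIGS, RESULTS, summaries_path

from reachplan.obstacle_models import frame_to_summaries
from reachplan.pipeline import cmd_analyze_obstacle, write_report


def main() -> None:
    cohorts = {v: frame_to_summaries(pd.read_csv(summaries_path(v)))
               for v in ("expt2a", "expt2b")}
    for variant, other in (("expt2a", "expt2b"), ("expt2b", "expt2a")):
        rep = cmd_analyze_obstacle(CONFIGS[variant], cohort=cohorts[variant],
                                   cross_cohort=cohorts[other])
        path = write_report(rep, RESULTS / f"obstacle_report_{variant}.json")
        b = rep["baseline"]
        print(f"{variant} (n = {rep['n']}): observed mu2 = "
              f"{rep['observed_mu2_mean']:+.2f} deg "
              f"(obstacle-free {rep['observed_mu2_free_mean']:+.2f})")
        print(f"  baseline predictions: PO {b['po']['prediction']:+.2f} deg "
              f"(MSE {b['po']['mse']:.1f}), MA {b['ma']['prediction']:+.2f} deg "
              f"(MSE {b['ma']['mse']:.1f}); prediction index "
              f"{b['prediction_index']:+.2f}")
        print(f"  fitted weights: alpha = {rep['fitted']['alpha']:.2f}, "
              f"beta = {rep['fitted']['beta']:.2f}")
        for fam, cv in rep["cross_validation"].items():
            print(f"  cross-validated {fam.upper()} (weight from {other}): "
                  f"MSE {cv['mse_cv']:.1f} vs own {cv['mse_self']:.1f} "
                  f"({cv['pct_mse_increase']:+.0f}%)")
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
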