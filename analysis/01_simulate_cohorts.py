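#!/usr/bin/env python
"""Generate the four synthetic cohorts and write their trial/summary tables.

Produces, under results/data/:
  * multi-FF trial tables for the main force-field cohort (n = 16, PO
    ground truth) and the dense-direction generalization cohort (n = 10);
  * obstacle-experiment summary and per-trial direction tables for the
    large-obstacle variant (n = 8) and the pared-down variant (n = 26),
    both under PO ground truth.
"""

from common import CONFIGS, DATA

from reachplan.pipeline import cmd_simulate


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for name, cfg in CONFIGS.items():
        paths = cmd_simulate(cfg, out_dir=DATA)
        sizes = {k: f"{p.stat().st_size / 1e3:.0f} kB" for k, p in paths.items()}
        print(f"{name}: wrote {sizes}")


if __name__ == "__main__":
    main()
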