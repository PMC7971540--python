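"""Time course of all nine species on the standard 50x30 μm teardrop.

Runs the standard left-to-right graded Cdc42 stimulus and writes
snapshots, the maximum-tracking series and rendered Cdc42 panels (white
above 3 μM).  Expected outcome: an initial right-edge Cdc42 maximum that
detaches and shifts left ("reverse polarization") after the 10-s
stimulus, while Rho stays anti-correlated with Cdc42.

Run:  python analysis/01_single_run_timecourse.py [--mesh 110] [--t-end 1000]
"""

import argparse

from shapepolar.scenarios import run_scenario

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--mesh", type=int, default=110)
    ap.add_argument("--t-end", type=float, default=1000.0)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = run_scenario("fig4_teardrop_timecourse", out_dir=args.out,
                       n_mesh=args.mesh, t_end=args.t_end)
    print(f"wrote teardrop time course to {out}")
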