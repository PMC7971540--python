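"""Stimulus strength/duration grid for the circle and teardrop.

Crosses the three intercepts (1.6, 2.6, 3.6 μM/s), three slopes (0.025,
0.05, 0.1 μM/s/μm) and durations (5, 10, 20 s, sustained) of the linear
activation gradient and classifies each outcome, probing how the initial
polarization strength shapes reverse polarization.

Run:  python analysis/03_stimulus_strength_duration.py [--mesh 72]
"""

import argparse

import pandas as pd

from shapepolar.scenarios import run_scenario

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--mesh", type=int, default=72)
    ap.add_argument("--t-end", type=float, default=1000.0)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()
    out = run_scenario("fig6_strength_duration", out_dir=args.out,
                       n_mesh=args.mesh, t_end=args.t_end)
    df = pd.read_csv(out / "strength_duration.csv")
    print(df.groupby(["shape", "label"]).size().unstack(fill_value=0))
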