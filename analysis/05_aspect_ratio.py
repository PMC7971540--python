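"""Aspect-ratio sweep: lengths x widths in 10-90 μm for teardrop,
ellipse and rectangle, classified into the six polarization patterns.

Expected trends: small cells polarize along whichever axis is longer;
medium lengths (30-60 μm) keep the stimulated direction; large lengths
(>60 μm) reverse-polarize along the initial axis; rectangles never
reverse when short; multi-front states appear in large stretched cells.

Run:  python analysis/05_aspect_ratio.py [--mesh 72] [--sizes 10,30,50,70,90]
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
    out = run_scenario("fig8_aspect_ratio", out_dir=args.out,
                       n_mesh=args.mesh, t_end=args.t_end)
    df = pd.read_csv(out / "aspect_ratio.csv")
    for shape, grp in df.groupby("shape"):
        print(f"\n{shape}:")
        print(grp.pivot_table(index="width", columns="length", values="pattern",
                              aggfunc="first").to_string())
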