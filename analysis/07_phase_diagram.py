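"""Phase diagrams over (a1, d_C) at Hill coefficients n = 1, 4, 8 for
the circle and teardrop.

Labels every lattice point uniform / normal / reverse from a full
1000-s run.  Expected structure: no reverse phase anywhere at n = 1;
for n = 4, 8 a reverse region at a1 > 0.5 and d_C > 0.1, similar for
both shapes.

Run:  python analysis/07_phase_diagram.py [--mesh 72]
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
    out = run_scenario("fig10_phase_diagram", out_dir=args.out,
                       n_mesh=args.mesh, t_end=args.t_end)
    df = pd.read_csv(out / "phase_diagram.csv")
    for (shape, n), grp in df.groupby(["shape", "n"]):
        print(f"\n{shape}, n={n}:")
        print(grp.pivot_table(index="a1", columns="d_C", values="label",
                              aggfunc="first").to_string())
        n_rev = (grp.label == "reverse").sum()
        print(f"reverse points: {n_rev}/{len(grp)}")
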