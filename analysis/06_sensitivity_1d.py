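"""One-at-a-time parameter sensitivity on circle and teardrop.

Varies PI feedback f, the GTPase inactivation rates, the Rho-on-Cdc42
inhibition threshold a1, the Hill coefficient n and the diffusion
coefficients, one parameter per series, and classifies each run.
Key expectations: no reverse polarization at n = 1; reverse vanishes at
both low (0.01-0.1/s) and high (10/s) Cdc42/Rho inactivation; a1 = 0.5
collapses the gradient.

Run:  python analysis/06_sensitivity_1d.py [--mesh 72]
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
    out = run_scenario("fig9_sensitivity", out_dir=args.out,
                       n_mesh=args.mesh, t_end=args.t_end)
    df = pd.read_csv(out / "sensitivity_1d.csv")
    print(df.pivot_table(index=["parameter", "value"], columns="shape",
                         values="label", aggfunc="first").to_string())
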