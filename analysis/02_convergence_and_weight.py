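"""Transfer efficiency vs thalamocortical convergence size and weight.

Sweeps the thalamic population size for fixed AMPA weights (and for the
matched N x w ~ 210 nS trade-off) and the weight for fixed sizes,
reporting where the retinocortical TE peaks. Reduced scale by default
(pass --scale 1 for the full protocol). Writes results/convergence_size.csv and
results/synaptic_weight.csv.
"""

import argparse
from pathlib import Path

from rtcnet.experiments import ExperimentSpec, find_optimum, run_experiment

OUT = Path("results")
OUT.mkdir(exist_ok=True)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.2)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    for exp in ("convergence_size", "synaptic_weight"):
        df = run_experiment(ExperimentSpec(exp, scale=args.scale,
                                           seed=args.seed),
                            out_path=OUT / f"{exp}.csv", log=print)
        if exp == "convergence_size":
            sub = df[df.weight == 2.33]
            point, te = find_optimum(sub, by="n_tc", smoothing=True)
            print(f"biological weight (2.33 nS): TE peaks at "
                  f"N = {point['n_tc']:.0f} cells ({te:.1f} bits/s)")
        else:
            for n in df.n_tc.unique():
                point, te = find_optimum(df[df.n_tc == n], by="weight",
                                         smoothing=True)
                print(f"N = {n}: optimal weight {point['weight']:.2f} nS "
                      f"({te:.1f} bits/s; N*w = {n * point['weight']:.0f} nS)")


if __name__ == "__main__":
    main()
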