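"""Calibration sweep for the Wright-Fisher polygamy probability.

Finds the ``polygamy_prob`` at which about one third of extant sibling
pairs are half-siblings (the summary level the polygamous experiments
assume).  The chosen value is frozen as
``pedrecon.simulate.DEFAULT_POLYGAMY_PROB``.

Usage: python scripts/calibrate_polygamy.py [--size 500] [--replicates 12]
"""

import argparse

import numpy as np

from pedrecon.simulate import WFConfig, halfsib_fraction, wf_pedigree


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--size", type=int, default=500)
    ap.add_argument("--generations", type=int, default=5)
    ap.add_argument("--replicates", type=int, default=12)
    ap.add_argument("--target", type=float, default=1 / 3)
    args = ap.parse_args()

    grid = np.round(np.arange(0.05, 0.31, 0.01), 2)
    best = None
    for p in grid:
        fractions = [
            halfsib_fraction(wf_pedigree(WFConfig(
                initial_size=args.size, final_size=args.size,
                generations=args.generations, polygamy_prob=float(p), seed=s)))
            for s in range(args.replicates)
        ]
        mean = float(np.mean(fractions))
        print(f"polygamy_prob={p:.2f}  half-sib fraction={mean:.3f}")
        if best is None or abs(mean - args.target) < best[1]:
            best = (float(p), abs(mean - args.target))
    print(f"closest to target {args.target:.3f}: polygamy_prob={best[0]:.2f}")


if __name__ == "__main__":
    main()
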