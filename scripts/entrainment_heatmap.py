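"""Entrainment-score grid for the repressilator-driven gene expression
circuit (scaled-down 4 x 4 version of the full heat-map).

The repressilator's spectrum is estimated once with the finite-point
rational method; the downstream circuit is linear, so every (theta, k_fb)
cell is evaluated analytically with the composite spectrum — no further
simulation is needed.

Usage:  python scripts/entrainment_heatmap.py [--seed 11] [--out grid.csv]
"""

import argparse
import sys

import numpy as np

from padepsd import composite_psd, entrainment_score, fixtures, linearize, pade_psd, peak_frequency


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--out", default=None)
    args = parser.parse_args(argv)

    up = pade_psd(fixtures.repressilator(H=1.5), p=3, s_points=(0.8, 2.4, 4.8, 10.0),
                  rho=(2, 2, 2, 2), test_points=(1.6, 4.0),
                  Q=10, T_f=600.0, T_c=30.0, seed=args.seed)
    w0 = peak_frequency(up.rational, omega_hi=8.0)
    ybar = up.derivatives.mean
    print(f"repressilator peak: {w0:.3f} rad/time, mean output {ybar:.1f} "
          f"(validation {'PASS' if up.validation.passed else 'FAIL'})", file=sys.stderr)

    thetas = [0.1, 0.3, 0.6, 1.0]
    kfbs = [0.05, 0.15, 0.3, 0.5]
    rows = []
    print("theta\\k_fb " + "  ".join(f"{k:7.2f}" for k in kfbs))
    for th in thetas:
        row = []
        for kfb in kfbs:
            down = fixtures.entrainment_circuit(k_fb=kfb, theta=th, upstream_mean=ybar)
            mats = linearize(down)

            def total(w, mats=mats, th=th):
                t, _, _ = composite_psd(mats, 1, up.rational.psd, th, [1, 0], w,
                                        upstream_mean=ybar)
                return t

            row.append(entrainment_score(total, w0))
        rows.append(row)
        print(f"{th:10.2f} " + "  ".join(f"{v:7.4f}" for v in row))

    if args.out:
        with open(args.out, "w") as fh:
            fh.write("theta,k_fb,score\n")
            for th, row in zip(thetas, rows):
                for kfb, v in zip(kfbs, row):
                    fh.write(f"{th},{kfb},{v}\n")
        print(f"wrote {args.out}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
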