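#!/usr/bin/env python
"""Estimator validation against generator ground truth.

Sweeps fibril diameter (40-120 nm), interfibrillar gap (5-40 nm),
D-band period (55-67 nm) and centerline tortuosity (amplitude 0 to
lambda/8) at default noise, measuring each image with the pipeline's
estimators, and sweeps the amorphous target fraction 0.10-0.30 for the
light-microscopy statistic. Writes per-image error tables and prints
median relative errors.
"""

import argparse
from pathlib import Path

from dermometry.simulations import amorphous_recovery, estimator_recovery_grid


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    grid = estimator_recovery_grid(seed=args.seed)
    amor = amorphous_recovery(seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    grid.to_csv(args.out / "estimator_recovery.csv", index=False)
    amor.to_csv(args.out / "amorphous_recovery.csv", index=False)

    print("median relative recovery error by estimator (%):")
    med = grid.groupby("variable")["rel_error"].median() * 100
    print(med.round(2).to_string())
    print(
        f"\namorphous %: max |measured - truth| = "
        f"{amor['error_pp'].max():.3f} pp over targets 0.10-0.30"
    )
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
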