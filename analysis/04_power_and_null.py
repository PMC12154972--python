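#!/usr/bin/env python
"""Statistical calibration: type-I error under the null and detection
power for the encoded HA effects.

Null: 200 replicate measurement cohorts with no group differences, full
comparison plan, both tests — the rejection rate should sit near the
nominal alpha = 0.05. Power: replicate two-group cohorts encoding the
reticular-24h HA effects at study sample sizes — each affected variable
should be detected in >= 90% of cohorts while D band stays null.
"""

import argparse
from pathlib import Path

from dermometry.simulations import reticular_effect_replicates
from dermometry.stats import null_rejection_rate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=12)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    for test in ("mann_whitney", "t_test"):
        rate = null_rejection_rate(200, n_per_group=20, test=test, seed=args.seed)
        print(f"type-I error ({test}): {rate:.3f} (nominal 0.05)")

    eff = reticular_effect_replicates(
        n_replicates=args.replicates, master_seed=args.seed
    )
    args.out.mkdir(parents=True, exist_ok=True)
    eff.to_csv(args.out / "effect_replicates.csv", index=False)
    rates = eff.groupby("variable")["significant"].mean()
    print(f"\ndetection rate over {args.replicates} replicate cohorts (CT vs HA, reticular 24 h):")
    print(rates.round(3).to_string())
    print("(d_band_length carries no effect; its rate is the false-positive rate)")
    print(f"table written to {args.out / 'effect_replicates.csv'}")


if __name__ == "__main__":
    main()
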