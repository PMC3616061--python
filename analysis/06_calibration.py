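#!/usr/bin/env python
"""Simulation-based calibration of the whole estimation chain.

Repeatedly simulates a study-scale dataset at known parameter values,
re-runs the estimators, and scores how often the 95% credible intervals
cover the generating truth — pooled over the per-colony densities λ,
occupancy τ, productivity θ, the carcass disappearance rate r and the
island burrow total.  Near-nominal coverage validates the chain where the
published point values cannot be reproduced (their raw counts were never
deposited).
"""

import argparse
from pathlib import Path

from shearwater_census.recovery import run_recovery_study


def run(seed: int, out_dir: Path, replicates: int) -> None:
    study = run_recovery_study(n_replicates=replicates, seed=seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    study.frame.to_csv(out_dir / "calibration.csv", index=False)
    print(f"{replicates} replicates, {study.n_trials} interval/truth trials")
    print(f"pooled 95% CI coverage: {study.pooled_coverage:.1%}")
    for family, cov in sorted(study.per_quantity.items()):
        print(f"  {family:<8} {cov:.1%}")
    print(f"fully counted colony always zero-variance: {study.zero_variance_ok}")
    print(f"per-trial table in {out_dir/'calibration.csv'}")


if __name__ == "__main__":
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=1)
    p.add_argument("--out-dir", type=Path, default=Path("results"))
    p.add_argument("--replicates", type=int, default=50)
    a = p.parse_args()
    run(a.seed, a.out_dir, a.replicates)
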