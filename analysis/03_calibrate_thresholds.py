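"""Calibrate the neutral significance thresholds for CLR_max and omega_max.

Simulates neutral European-sample replicates of the full region under the
three-population bottleneck model, estimates the neutral background
spectrum from one batch, and takes the 95th percentile of the maximum CLR
and omega statistics over a second batch.  Optionally repeats the exercise
at alternative mutation rates to show how strongly the thresholds depend on
this unprinted quantity (they scale roughly with the number of segregating
sites).

Writes results/thresholds.json.
"""

import argparse
import json
from pathlib import Path

from sweepvalley import DemographicModel, simulate
from sweepvalley.coalsim import calibrate_thresholds
from sweepvalley.sweep_clr import background_from_simulations, clr_max_statistic
from sweepvalley.sweep_omega import omega_max_statistic

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
L = 20011


def calibrate(model, reps, seed):
    sims = [simulate(model, {"EU": 12}, L, seed=seed + 100_000 + s)
            for s in range(max(40, reps // 10))]
    background = background_from_simulations(sims, 12)
    stats = {"clr_max": clr_max_statistic(background),
             "omega_max": omega_max_statistic()}
    thresholds, _ = calibrate_thresholds(model, {"EU": 12}, L, stats,
                                         reps=reps, q=0.95, seed=seed)
    return thresholds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=400)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--mu-sensitivity", action="store_true",
                    help="recalibrate at 0.5x and 2x the default mu")
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    model = DemographicModel()
    out = {"reps": args.reps, "mu": model.mu,
           "thresholds": calibrate(model, args.reps, args.seed)}
    print(f"mu={model.mu:.2e}: TH_CLR = {out['thresholds']['clr_max']:.1f}, "
          f"TH_omega = {out['thresholds']['omega_max']:.1f}")

    if args.mu_sensitivity:
        out["sensitivity"] = {}
        for f in (0.5, 2.0):
            m2 = model.with_params(mu=model.mu * f)
            th = calibrate(m2, args.reps, args.seed)
            out["sensitivity"][f"mu_x{f}"] = th
            print(f"mu x{f}: TH_CLR = {th['clr_max']:.1f}, "
                  f"TH_omega = {th['omega_max']:.1f}")

    (RESULTS / "thresholds.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
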