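"""Scan the (synthetic) study region for a selective sweep.

Takes the swept region from 01 (regenerated with the same seed), runs the
CLR scan with the simulation-estimated neutral background and the omega
scan over 2-10-kb windows, and compares both maxima against the calibrated
thresholds from 03 (falling back to a quick calibration if missing).

Writes results/clr_scan.tsv and results/omega_scan.tsv.
"""

import json
import sys
from pathlib import Path

from sweepvalley import (
    DemographicModel,
    SweepSpec,
    classify_sites,
    generate_sweep_region,
    simulate,
)
from sweepvalley.sweep_clr import background_from_simulations, clr_scan
from sweepvalley.sweep_omega import haplotypes_from_alignment, omega_scan

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
L = 20011


def main(seed: int = 11) -> None:
    RESULTS.mkdir(exist_ok=True)
    model = DemographicModel()
    aln = generate_sweep_region(model, samples={"EU": 12, "AF": 12},
                                sweep=SweepSpec(population="EU"), seed=seed)
    table = classify_sites(aln)

    sims = [simulate(model, {"EU": 12}, L, seed=400_000 + s) for s in range(60)]
    background = background_from_simulations(sims, 12)

    thr_file = RESULTS / "thresholds.json"
    thresholds = (json.loads(thr_file.read_text())["thresholds"]
                  if thr_file.exists() else None)

    clr = clr_scan(table, background, "EU")
    clr.to_dataframe().to_csv(RESULTS / "clr_scan.tsv", sep="\t", index=False)
    omega = omega_scan(haplotypes_from_alignment(aln, "EU", table=table))
    omega.to_dataframe().to_csv(RESULTS / "omega_scan.tsv", sep="\t",
                                index=False)

    msg = [f"CLR_max = {clr.max_value:.1f} at {clr.argmax_position:.0f} bp",
           f"omega_max = {omega.max_value:.1f} at {omega.argmax_position:.0f} bp"]
    if thresholds:
        msg[0] += (" (significant)" if clr.max_value > thresholds["clr_max"]
                   else " (not significant)")
        msg[1] += (" (significant)"
                   if omega.max_value > thresholds["omega_max"]
                   else " (not significant)")
    print("\n".join(msg))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
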