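"""Simulate the study region and profile its diversity landscape.

Generates a 20,011-bp two-population region with an outgroup at ~6%
divergence and a completed sweep injected into the European sample at the
region centre, then reproduces the sliding-window analysis: per-window S,
pi, theta_W, Tajima's D and divergence for both populations, region means,
and a Wilcoxon comparison of the swept sample's non-overlapping windows
against windows from a neutral control region.

Writes results/window_stats_{EU,AF}.tsv and results/region_summary.json;
the alignment itself goes to scratch/ (it is bulky and regenerable).
"""

import json
import sys
from pathlib import Path

import numpy as np

from sweepvalley import (
    DemographicModel,
    SweepSpec,
    classify_sites,
    generate_sweep_region,
    sliding_windows,
    wilcoxon_window_test,
    write_alignment,
)
from sweepvalley.popgen_stats import divergence, windows_to_dataframe

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main(seed: int = 11) -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    model = DemographicModel()

    swept = generate_sweep_region(model, samples={"EU": 12, "AF": 12},
                                  sweep=SweepSpec(population="EU"), seed=seed)
    control = generate_sweep_region(model, samples={"EU": 12, "AF": 12},
                                    seed=seed + 1)
    write_alignment(swept, SCRATCH / "region_swept.fasta")

    table = classify_sites(swept)
    summary = {"seed": seed, "L": swept.L}
    for pop in ("EU", "AF"):
        ws = sliding_windows(table, pop)
        windows_to_dataframe(ws).to_csv(
            RESULTS / f"window_stats_{pop}.tsv", sep="\t", index=False)
        summary[f"theta_w_mean_{pop}"] = float(
            np.mean([w.theta_w for w in ws]))
        dvals = [w.tajima_d for w in ws if w.tajima_d is not None]
        summary[f"tajima_d_mean_{pop}"] = float(np.mean(dvals)) if dvals else None
        summary[f"divergence_{pop}"] = divergence(table, pop)

    # Wilcoxon on non-overlapping windows: swept EU vs neutral-control EU
    ctrl_ws = sliding_windows(classify_sites(control), "EU")
    region = [w.theta_w for w in sliding_windows(table, "EU") if (w.start - 1) % 1000 == 0]
    baseline = [w.theta_w for w in ctrl_ws if (w.start - 1) % 1000 == 0]
    W, p = wilcoxon_window_test(region, baseline)
    summary["wilcoxon_W"] = W
    summary["wilcoxon_p"] = p

    (RESULTS / "region_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"region means: theta_E = {summary['theta_w_mean_EU']:.4f}, "
          f"theta_A = {summary['theta_w_mean_AF']:.4f}; "
          f"divergence ~ {summary['divergence_EU']:.3f}")
    print(f"swept-vs-neutral window diversity: Wilcoxon p = {p:.4f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
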