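#!/usr/bin/env python
"""Render figures from the finished analysis tables.

Signed-amplitude-vs-eccentricity panels per condition (error bars from
the origin-to-ellipse bounds, stars on significant bands), example cycle
averages for the most significant positive and negative sub-ROIs of the
contrast condition (with the NaN-padding path exercised for the
block-order-reversed disparity condition), and a delay histogram over the
significant whole-brain nodes.  Plotting only — every number comes from
the tables written by the earlier steps.
"""

from pathlib import Path

import pandas as pd

from freqtag.pipeline import AnalysisConfig, participant_response, report
from freqtag.simulate import load_cohort
from freqtag.spectral import cycle_average

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
FIGURES = SCRATCH / "figures"


def best_band_cycle_averages(table: pd.DataFrame) -> dict:
    """Cycle averages for the lowest-p positive and negative contrast bands."""
    out = {}
    ecc = pd.read_csv(SCRATCH / "cohorts" / "eccentricity_map.tsv", sep="\t")
    for condition, nan_pad in (("contrast", 0), ("disparity", 6)):
        cohort = load_cohort(SCRATCH / "cohorts" / condition)
        sub = table[(table["condition"] == condition) & table["significant"]]
        for label, grp in (("pos", sub[sub["sign"] > 0]),
                           ("neg", sub[sub["sign"] < 0])):
            if grp.empty:
                continue
            row = grp.loc[grp["p_value"].idxmin()]
            area, center = row["area"], row["center"]
            verts = ecc[(ecc["area"] == area)
                        & ((ecc["eccentricity_deg"] - center).abs() <= 0.25)]
            roi = verts["vertex_id"].tolist()
            cfg = AnalysisConfig()
            means = []
            for scans in cohort["scans"].values():
                _, roi_ts = participant_response(scans, roi, cfg)
                ca = cycle_average(roi_ts, cfg.samples_per_cycle,
                                   nan_pad=nan_pad)
                means.append(ca.mean)
            group = pd.DataFrame(means)
            ca.mean = group.mean().to_numpy()
            ca.sem = (group.std(ddof=1) / len(group) ** 0.5).to_numpy()
            out[f"{condition}_{label}_{row['roi']}"] = ca
    return out


def main() -> None:
    table = pd.read_csv(RESULTS / "subroi_table.tsv", sep="\t")
    delays = pd.read_csv(SCRATCH / "wholebrain_nodes.tsv", sep="\t")
    cycles = best_band_cycle_averages(table)
    written = report(table, FIGURES, cycle_averages=cycles,
                     delay_table=delays)
    for p in written:
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
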