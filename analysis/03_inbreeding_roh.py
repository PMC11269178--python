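#!/usr/bin/env python
"""Profile runs of homozygosity and flag close-kin mating.

Simulates two cohorts on 25-cM chromosomes — one whose diploids are
self-paired haploids (the extreme of close-kin mating) and one of outbred
random-paired diploids from a large population — then computes two-draw
pseudo-heterozygosity in 1-cM windows, calls ROH (rate < 0.005), bins
segment lengths into the standard size classes and reports the close-kin
flag (any segment >= 15 cM).

Output: results/03_roh_summary.tsv (one row per simulated genome).
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from paleoclock.genmap import GeneticMap, make_windows
from paleoclock.roh import (call_roh, pseudo_het_profile, summarize_roh,
                            two_draws_from_cohort)
from paleoclock.simdata import (DemographyScenario, SimulationDesign,
                                simulate_cohort)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--threshold", type=float, default=0.005)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1])
    args = ap.parse_args()

    big_ne = DemographyScenario("big", ((0, 10_000.0),))
    gmap = GeneticMap.uniform({"1": 25e6, "2": 25e6})
    windows = make_windows(gmap, 1.0)
    frames = []
    for tag, self_pair, s in (("self_paired", True, args.seed),
                              ("outbred", False, args.seed + 50)):
        design = SimulationDesign(n_chromosomes=2, chrom_length=25e6,
                                  sample_times=(0.0,), haploids_per_time=12,
                                  self_pair_most_recent=self_pair, seed=s)
        cohort, _ = simulate_cohort(design, big_ne)
        draws = two_draws_from_cohort(cohort, seed=s + 1)
        prof = pseudo_het_profile(draws, cohort.positions, cohort.sample_ids,
                                  gmap, windows)
        segs = call_roh(prof, windows, threshold=args.threshold)
        summ = summarize_roh(segs, gmap.total_span_cM(), cohort.sample_ids)
        summ.insert(0, "cohort", tag)
        frames.append(summ)
    out = pd.concat(frames, ignore_index=True)

    res_dir = args.out / "results"
    res_dir.mkdir(exist_ok=True)
    out.to_csv(res_dir / "03_roh_summary.tsv", sep="\t", index=False)

    by = out.groupby("cohort")[["f_total", "f_15_inf", "close_kin"]].mean()
    print(by.round(4).to_string())
    print("self-paired genomes sit almost entirely in >=15 cM ROH "
          "(close_kin = True); outbred genomes carry none")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
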