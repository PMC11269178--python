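#!/usr/bin/env python
"""Run the canonical site-filter pipeline on the simulated cohort VCF.

Reads the cohort exported by 01_simulate_cohort.py (or regenerates it) and
applies the ancient-DNA filter cascade — transversions only, outgroup
polarization, 30% missingness, adjacent-site thinning — recording the site
count after each stage. In this synthetic cohort every variant is already a
correctly polarized transversion, so the pipeline's attrition comes from the
missingness and adjacency rules alone; the stage report is the point.

Output: results/02_filter_report.tsv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from paleoclock.genotypes import (downsample_calls, filter_missingness,
                                  filter_transversions, polarize, read_vcf,
                                  thin_adjacent)
from paleoclock.simdata import (DemographyScenario, SimulationDesign,
                                pseudo_haploidize_cohort, simulate_cohort)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--keep-prob", type=float, default=0.8,
                    help="per-call retention emulating coverage dropout")
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1])
    args = ap.parse_args()

    vcf = args.out / "scratch" / "sim" / "cohort.vcf"
    if vcf.exists():
        matrix = read_vcf(vcf)
        print(f"read {vcf}")
    else:
        design = SimulationDesign(seed=args.seed)
        scenario = DemographyScenario("const1k", ((0, 1000.0),))
        cohort, _ = simulate_cohort(design, scenario)
        matrix = pseudo_haploidize_cohort(cohort, seed=args.seed + 1)
        print("cohort VCF absent; regenerated deterministically")

    stages = [("input", matrix)]
    m = downsample_calls(matrix, args.keep_prob, seed=args.seed + 2)
    stages.append((f"dropout (keep {args.keep_prob:g})", m))
    m = filter_transversions(m)
    stages.append(("transversions", m))
    og = pd.DataFrame({"chrom": m.sites["chrom"], "pos": m.sites["pos"],
                       "og1": m.sites["anc"], "og2": m.sites["anc"],
                       "og3": m.sites["anc"]})     # simulator-truth outgroups
    m = polarize(m, og)
    stages.append(("polarized", m))
    m = filter_missingness(m, 0.30)
    stages.append(("missingness < 30%", m))
    m = thin_adjacent(m, seed=args.seed + 3)
    stages.append(("adjacent-thinned", m))

    report = pd.DataFrame({
        "stage": [s for s, _ in stages],
        "n_sites": [mm.n_sites for _, mm in stages],
    })
    res_dir = args.out / "results"
    res_dir.mkdir(exist_ok=True)
    report.to_csv(res_dir / "02_filter_report.tsv", sep="\t", index=False)
    print(report.to_string(index=False))
    print("site counts are monotone non-increasing along the cascade")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
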