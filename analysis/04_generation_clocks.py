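#!/usr/bin/env python
"""Estimate per-genome generation counts with both molecular clocks.

On a serial constant-Ne cohort: the mutation clock (derived-mutation density
over mu) and the recombination clock (shared derived-pair decay curve with
per-genome amplitudes), with leave-one-chromosome-out jackknife errors for
the recombination clock, compared against the simulator's genealogical
truth.

Outputs: results/04_clock_estimates.tsv (per sample),
results/04_decay_curve.tsv (fitted shared root-height covariance profile),
results/04_clock_recovery.tsv (per-time-bin recovery summary).
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from paleoclock.clocks import (ClockConfig, desk_scale_bins,
                               fit_recombination_clock, jackknife_recclock,
                               mutation_clock, pair_curves)
from paleoclock.genmap import GeneticMap
from paleoclock.simdata import (DemographyScenario, SimulationDesign,
                                pseudo_haploidize_cohort, simulate_cohort)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1])
    args = ap.parse_args()

    design = SimulationDesign(seed=args.seed)
    scenario = DemographyScenario("const1k", ((0, 1000.0),))
    cohort, truth = simulate_cohort(design, scenario)
    matrix = pseudo_haploidize_cohort(cohort, seed=args.seed + 1)
    gmap = GeneticMap.uniform({c: design.chrom_length
                               for c in cohort.chrom_names})
    cfg = ClockConfig(mu=design.mut_rate, distance_bins=desk_scale_bins(),
                      seed=args.seed)

    mc = mutation_clock(matrix, cfg)
    fit = fit_recombination_clock(pair_curves(matrix, gmap, cfg), cfg, mc)
    jk = jackknife_recclock(matrix, gmap, cfg, mc)

    tr = truth.table.set_index("sample")
    per_sample = (mc.set_index("sample")
                  .join(fit.t_i.rename("t_i"))
                  .join(fit.p_i.rename("p_i"))
                  .join(jk.set_index("sample")["var_jk"]
                        .rename("t_var_jk"))
                  .join(tr[["time_gen", "mean_path_gen"]])
                  .reset_index())

    res_dir = args.out / "results"
    res_dir.mkdir(exist_ok=True)
    per_sample.to_csv(res_dir / "04_clock_estimates.tsv", sep="\t",
                      index=False)
    pd.DataFrame({"mid_mM": fit.decay_mid_mM, "C_gen2": fit.decay_C}).to_csv(
        res_dir / "04_decay_curve.tsv", sep="\t", index=False)

    recovery = (per_sample.groupby("time_gen")
                .agg(true_path=("mean_path_gen", "mean"),
                     g_mut=("g_mut", "mean"), t_rec=("t_i", "mean"))
                .reset_index())
    recovery.to_csv(res_dir / "04_clock_recovery.tsv", sep="\t", index=False)

    rho = spearmanr(per_sample["t_i"], per_sample["mean_path_gen"]).statistic
    gap = (recovery.set_index("time_gen")["t_rec"].loc[0.0]
           - recovery.set_index("time_gen")["t_rec"].loc[900.0])
    print(recovery.round(1).to_string(index=False))
    print(f"recombination clock: rank corr with truth {rho:.3f}; "
          f"t(bin 0) - t(bin 900) = {gap:.0f} generations (truth: 900)")
    print(f"global scale T = {fit.T:.1f}; converged: {fit.converged}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
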