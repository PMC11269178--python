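"""Serially sampled coalescent cohorts with pseudo-haploidization.

This module emulates the validation design used throughout the package:
haploid lineages are sampled every ``dt`` generations under a configurable
single-population demography, paired into diploids within each time bin
(random mating), with the most recent bin self-paired to mimic the elevated
inbreeding of modern cohorts, and finally pseudo-haploidized — one uniformly
drawn allele per site per sample.

The genealogical truth table records, for every diploid, the mean
root-to-sample path length in generations (averaged across loci and the two
haploid copies), which is the quantity both clocks estimate. All simulated
variants are generated under an infinite-sites binary model and treated as
transversions; the real-data transversion filter is an ascertainment step
orthogonal to the clocks.

Default scale is a desk-size genome (4 chromosomes x 10 Mb); the full-scale
design (31 x 75 Mb) is reachable through :class:`SimulationDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .genotypes import SiteMatrix

__all__ = [
    "DemographyScenario",
    "SimulationDesign",
    "DiploidCohort",
    "CohortTruth",
    "SCENARIOS",
    "simulate_cohort",
    "pair_haploids",
    "pseudo_haploidize_cohort",
    "true_path_generations",
]


@dataclass(frozen=True)
class DemographyScenario:
    """Piecewise-constant single-population demography.

    ``epochs`` is an ordered list of (start_time in generations before
    present, diploid Ne); the first epoch must start at time 0 and start
    times must strictly increase into the past.
    """

    id: str
    epochs: tuple[tuple[float, float], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("scenario needs at least one epoch")
        times = [t for t, _ in self.epochs]
        if times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("epoch start times must strictly increase")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be positive")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=self.epochs[0][1])
        for start, ne in self.epochs[1:]:
            dem.add_population_parameters_change(time=start, initial_size=ne,
                                                 population="pop")
        return dem


def _default_scenarios() -> dict[str, DemographyScenario]:
    """Ten stock demographies: constant sizes, contractions and expansions of
    various magnitudes and onset times, with and without recovery."""
    base = 10_000.0
    s = [
        DemographyScenario("constant", ((0, base),), "constant Ne"),
        DemographyScenario("contraction_5x_200", ((0, base / 5), (200, base)),
                           "5-fold contraction 200 generations ago"),
        DemographyScenario("contraction_10x_200", ((0, base / 10), (200, base)),
                           "10-fold contraction 200 generations ago"),
        DemographyScenario("contraction_50x_200", ((0, base / 50), (200, base)),
                           "50-fold contraction 200 generations ago"),
        DemographyScenario("contraction_10x_500", ((0, base / 10), (500, base)),
                           "10-fold contraction 500 generations ago"),
        DemographyScenario("expansion_5x_200", ((0, base * 5), (200, base)),
                           "5-fold expansion 200 generations ago"),
        DemographyScenario("expansion_10x_200", ((0, base * 10), (200, base)),
                           "10-fold expansion 200 generations ago"),
        DemographyScenario("expansion_10x_500", ((0, base * 10), (500, base)),
                           "10-fold expansion 500 generations ago"),
        DemographyScenario("contraction_recovery",
                           ((0, base), (100, base / 10), (400, base)),
                           "10-fold contraction at 400, recovered by 100 generations ago"),
        DemographyScenario("expansion_recovery",
                           ((0, base), (100, base * 10), (400, base)),
                           "10-fold expansion at 400, back to base by 100 generations ago"),
    ]
    return {sc.id: sc for sc in s}


SCENARIOS: dict[str, DemographyScenario] = _default_scenarios()


@dataclass(frozen=True)
class SimulationDesign:
    """Sampling design and genome parameters for a serial cohort."""

    n_chromosomes: int = 4
    chrom_length: float = 10e6
    recomb_rate: float = 1e-8
    mut_rate: float = 2.3e-8
    sample_times: tuple[float, ...] = tuple(float(t) for t in range(0, 1000, 100))
    haploids_per_time: int = 20
    self_pair_most_recent: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.recomb_rate <= 0 or self.mut_rate <= 0:
            raise ValueError("lengths and rates must be positive")
        if any(t < 0 for t in self.sample_times):
            raise ValueError("sample times must be non-negative")
        if list(self.sample_times) != sorted(self.sample_times):
            raise ValueError("sample times must be sorted ascending")
        if self.haploids_per_time % 2:
            raise ValueError("haploids_per_time must be even for random pairing")


@dataclass
class DiploidCohort:
    """Per-chromosome haplotypes plus the haploid->diploid pairing.

    ``haplotypes[chrom]`` is a (n_sites x n_haploids) 0/1 array over
    segregating sites (0 = true ancestral allele); ``positions[chrom]`` are
    1-based bp. ``pairs`` maps each diploid to its two haploid column indices
    (equal for self-paired diploids).
    """

    chrom_names: list[str]
    chrom_length: float
    positions: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]
    pairs: np.ndarray                 # (n_diploids, 2) haploid column indices
    sample_times: np.ndarray          # per diploid, generations before present
    sample_ids: list[str]
    haploid_times: np.ndarray = field(default=None)

    @property
    def n_diploids(self) -> int:
        return len(self.sample_ids)

    def diploid_genotypes(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(n_sites x n_diploids) allele arrays for the two haploid copies."""
        h = self.haplotypes[chrom]
        return h[:, self.pairs[:, 0]], h[:, self.pairs[:, 1]]


@dataclass
class CohortTruth:
    """Genealogical truth per diploid sample.

    ``mean_path_gen`` is the root-to-sample genealogical path length in
    generations, averaged across loci (span-weighted across marginal trees
    and chromosomes) and across the diploid's two haploid copies.
    """

    table: pd.DataFrame  # columns: sample, time_gen, mean_path_gen

    def path(self, sample: str) -> float:
        sub = self.table.loc[self.table["sample"] == sample, "mean_path_gen"]
        if sub.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return float(sub.iloc[0])


def true_path_generations(truth: CohortTruth, sample: str) -> float:
    """Mean root-to-sample genealogical length in generations for a sample."""
    return truth.path(sample)


def pair_haploids(haploid_ids: np.ndarray, *, self_pair: bool,
                  rng: np.random.Generator) -> np.ndarray:
    """Pair haploids within one time bin into diploids.

    Random pairing uses each haploid exactly once (even count required);
    self-pairing duplicates every haploid into a fully homozygous diploid.
    """
    ids = np.asarray(haploid_ids)
    if self_pair:
        return np.column_stack([ids, ids])
    if len(ids) % 2:
        raise ValueError("odd haploid count cannot be randomly paired")
    perm = rng.permutation(ids)
    return perm.reshape(-1, 2)


def _simulate_chromosome(design: SimulationDesign, scenario: DemographyScenario,
                         seed: int):
    samples = [msprime.SampleSet(design.haploids_per_time, time=t, ploidy=1)
               for t in design.sample_times]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=scenario.to_msprime(),
        sequence_length=design.chrom_length,
        recombination_rate=design.recomb_rate,
        ploidy=2,
        random_seed=seed % (2**31 - 2) + 1,
    )
    ts = msprime.sim_mutations(
        ts, rate=design.mut_rate, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=(seed + 1) % (2**31 - 2) + 1,
    )
    # span-weighted mean marginal-root time; sample-to-root path length is
    # this minus the sampling time (single root per marginal tree)
    root_time = 0.0
    for tree in ts.trees():
        root_time += tree.span * tree.time(tree.root)
    root_time /= ts.sequence_length
    # infinite-sites float positions -> unique integer bp (1-based)
    pos = np.floor(ts.sites_position).astype(np.int64) + 1
    gm = ts.genotype_matrix()  # sites x haploids, 0/1
    keep = np.concatenate([[True], np.diff(pos) > 0])
    gm = gm[keep]
    pos = pos[keep]
    # guard against back mutations from the binary model: keep strictly 0/1
    ok = (gm.max(axis=1) <= 1)
    return pos[ok], gm[ok].astype(np.int8), root_time


def simulate_cohort(design: SimulationDesign,
                    scenario: DemographyScenario) -> tuple[DiploidCohort, CohortTruth]:
    """Simulate a serially sampled, diploid-paired cohort with truth table.

    Chromosomes are simulated independently with seeds split hierarchically
    from ``design.seed``; with the seed fixed the output is reproducible.
    """
    ss = np.random.SeedSequence(design.seed)
    chrom_seeds = ss.generate_state(design.n_chromosomes + 1)
    pair_rng = np.random.default_rng(chrom_seeds[-1])

    n_bins = len(design.sample_times)
    hap_times = np.repeat(np.asarray(design.sample_times, dtype=float),
                          design.haploids_per_time)

    # pairing is shared across chromosomes (haploid index = sampling order)
    pairs_list, dip_times = [], []
    for b, t in enumerate(design.sample_times):
        ids = np.arange(b * design.haploids_per_time,
                        (b + 1) * design.haploids_per_time)
        self_pair = design.self_pair_most_recent and b == 0
        p = pair_haploids(ids, self_pair=self_pair, rng=pair_rng)
        pairs_list.append(p)
        dip_times.extend([t] * len(p))
    pairs = np.vstack(pairs_list)
    dip_times = np.asarray(dip_times, dtype=float)
    sample_ids = [f"t{int(t)}_d{i}" for i, t in enumerate(dip_times)]

    chrom_names = [str(c + 1) for c in range(design.n_chromosomes)]
    positions, haplotypes = {}, {}
    root_times = np.zeros(design.n_chromosomes)
    for c, name in enumerate(chrom_names):
        pos, gm, rt = _simulate_chromosome(design, scenario, int(chrom_seeds[c]))
        positions[name], haplotypes[name], root_times[c] = pos, gm, rt

    mean_root = float(root_times.mean())  # equal-length chromosomes
    mean_path = mean_root - dip_times     # both copies share the sampling time
    truth = CohortTruth(pd.DataFrame({
        "sample": sample_ids, "time_gen": dip_times, "mean_path_gen": mean_path,
    }))
    cohort = DiploidCohort(chrom_names, design.chrom_length, positions,
                           haplotypes, pairs, dip_times, sample_ids,
                           haploid_times=hap_times)
    if (mean_path <= 0).any():
        raise RuntimeError("sample time older than the mean genealogical root")
    return cohort, truth


def pseudo_haploidize_cohort(cohort: DiploidCohort, seed: int = 0) -> SiteMatrix:
    """One uniformly drawn allele per site per diploid, as a SiteMatrix.

    Calls are polarized to the simulator's true ancestral allele (perfect
    outgroup); every simulated variant is labelled as an A/T transversion.
    The callable length per sample is the full simulated genome.
    """
    rng = np.random.default_rng(seed)
    site_frames, call_blocks = [], []
    for chrom in cohort.chrom_names:
        a, b = cohort.diploid_genotypes(chrom)
        pick = rng.integers(0, 2, size=a.shape).astype(bool)
        calls = np.where(pick, b, a).astype(np.int8)  # sites x diploids
        call_blocks.append(calls.T)
        site_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": cohort.positions[chrom],
            "anc": "A", "der": "T",
        }))
    sites = pd.concat(site_frames, ignore_index=True)
    calls = np.hstack(call_blocks)
    samples = pd.DataFrame({
        "id": cohort.sample_ids,
        "group": [f"bin{int(t)}" for t in cohort.sample_times],
        "date": cohort.sample_times,
        "depth": 1.0,
    })
    lengths = {c: float(cohort.chrom_length) for c in cohort.chrom_names}
    return SiteMatrix(sites, calls, samples, lengths)


# ---------------------------------------------------------------------------
# Export helpers (plain-text outputs for the analysis drivers)


def write_truth_tsv(truth: CohortTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)
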