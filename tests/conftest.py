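"""Shared fixtures: small simulated cohorts and constructed site matrices."""

import numpy as np
import pandas as pd
import pytest

from paleoclock.genmap import GeneticMap
from paleoclock.genotypes import SiteMatrix
from paleoclock.simdata import (DemographyScenario, SimulationDesign,
                                pseudo_haploidize_cohort, simulate_cohort)

CONST_NE_1K = DemographyScenario("const1k", ((0, 1000.0),),
                                 "constant Ne=1000 test demography")


@pytest.fixture(scope="session")
def small_cohort():
    """Two-chromosome serial cohort under constant Ne=1,000 (desk scale)."""
    design = SimulationDesign(n_chromosomes=2, chrom_length=5e6, seed=7)
    cohort, truth = simulate_cohort(design, CONST_NE_1K)
    return design, cohort, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    design, cohort, truth = small_cohort
    return pseudo_haploidize_cohort(cohort, seed=11)


@pytest.fixture(scope="session")
def uniform_map(small_cohort):
    design, cohort, _ = small_cohort
    return GeneticMap.uniform({c: design.chrom_length for c in cohort.chrom_names})


def build_matrix(calls, positions=None, chroms=None, anc=None, der=None,
                 chrom_lengths=None):
    """Construct a SiteMatrix from a raw call array (samples x sites)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    positions = list(positions) if positions is not None else list(
        range(100, 100 + n_sites))
    chroms = list(chroms) if chroms is not None else ["1"] * n_sites
    sites = pd.DataFrame({
        "chrom": chroms,
        "pos": positions,
        "anc": anc if anc is not None else ["A"] * n_sites,
        "der": der if der is not None else ["T"] * n_sites,
    })
    samples = pd.DataFrame({
        "id": [f"s{i}" for i in range(n_samples)],
        "group": "g", "date": 0.0, "depth": 1.0,
    })
    if chrom_lengths is None:
        chrom_lengths = {c: 1e6 for c in dict.fromkeys(chroms)}
    return SiteMatrix(sites, calls, samples, chrom_lengths)
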