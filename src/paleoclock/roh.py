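"""Windowed pseudo-heterozygosity, ROH calling and close-kin flags.

Inbreeding is profiled without population allele frequencies: at every
informative site two alleles are drawn independently (two sequencing reads in
real mode; two seeded draws from the diploid genotype in synthetic mode) and
the mismatch rate is computed within 1-cM genetic windows. Windows with a
pseudo-heterozygosity rate strictly below the ROH threshold (default 0.005)
are runs of homozygosity; maximal runs of contiguous ROH windows merge into
segments, and the genome fraction in long segments (>= 15 cM) flags
close-kin mating.

Note that two independent draws detect a true heterozygous site only with
probability 1/2, so windowed rates sit at half the true heterozygosity; the
ROH threshold is calibrated on the same two-draw scale, so no correction is
applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import GeneticMap, Window, assign_windows
from .simdata import DiploidCohort

__all__ = [
    "SIZE_CLASSES",
    "two_draws_from_cohort",
    "pseudo_het_profile",
    "call_roh",
    "summarize_roh",
]

# half-open ROH length classes in cM; the last is [15, inf)
SIZE_CLASSES: tuple[tuple[float, float], ...] = (
    (1, 2), (2, 4), (4, 8), (8, 15), (15, np.inf),
)


def two_draws_from_cohort(cohort: DiploidCohort, seed: int = 0
                          ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Two independent seeded allele draws per site per diploid.

    Returns per chromosome a pair of (n_sites x n_diploids) allele arrays,
    mirroring the two-read sampling applied to real alignments.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for chrom in cohort.chrom_names:
        a, b = cohort.diploid_genotypes(chrom)
        draw1 = np.where(rng.integers(0, 2, size=a.shape).astype(bool), b, a)
        draw2 = np.where(rng.integers(0, 2, size=a.shape).astype(bool), b, a)
        out[chrom] = (draw1, draw2)
    return out


def pseudo_het_profile(draws: dict[str, tuple[np.ndarray, np.ndarray]],
                       positions: dict[str, np.ndarray],
                       sample_ids: list[str],
                       gmap: GeneticMap,
                       windows: list[Window],
                       min_sites: int = 20) -> pd.DataFrame:
    """Per-sample, per-window pseudo-heterozygosity rates.

    ``draws[chrom]`` holds two (n_sites x n_samples) allele arrays; sites
    where either draw is negative are uninformative for that sample. Windows
    with fewer than ``min_sites`` informative sites get rate NaN (missing).

    Returns a DataFrame with columns sample, window (index into ``windows``),
    chrom, rate, n_sites.
    """
    n_samples = len(sample_ids)
    n_win = len(windows)
    mismatch = np.zeros((n_samples, n_win))
    informative = np.zeros((n_samples, n_win))
    for chrom, (d1, d2) in draws.items():
        widx = assign_windows(gmap, windows, chrom, positions[chrom])
        ok_w = widx >= 0
        valid = (d1 >= 0) & (d2 >= 0) & ok_w[:, None]
        mism = valid & (d1 != d2)
        for s in range(n_samples):
            informative[s] += np.bincount(widx[valid[:, s]], minlength=n_win)
            mismatch[s] += np.bincount(widx[mism[:, s]], minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(informative >= min_sites, mismatch / informative, np.nan)
    recs = []
    for s, sid in enumerate(sample_ids):
        for w in range(n_win):
            recs.append((sid, w, windows[w].chrom, rate[s, w], int(informative[s, w])))
    return pd.DataFrame(recs, columns=["sample", "window", "chrom", "rate", "n_sites"])


def call_roh(profile: pd.DataFrame, windows: list[Window],
             threshold: float = 0.005) -> pd.DataFrame:
    """Merge runs of contiguous low-heterozygosity windows into ROH segments.

    A window is ROH when its rate is strictly below ``threshold``; missing
    (NaN) windows break runs rather than bridging them. Segment boundaries
    are reported at window edges.

    Returns a DataFrame with columns sample, chrom, start_cM, end_cM,
    start_bp, end_bp, length_cM.
    """
    segs = []
    for sid, sub in profile.groupby("sample", sort=False):
        sub = sub.sort_values("window")
        widx = sub["window"].to_numpy()
        is_roh = (sub["rate"].to_numpy() < threshold)  # NaN compares False
        run_start = None
        prev = None
        for w, flag in zip(widx, is_roh):
            contiguous = (
                prev is not None and w == prev + 1
                and windows[w].chrom == windows[prev].chrom
            )
            if flag and run_start is not None and contiguous:
                prev = w
                continue
            if run_start is not None:
                segs.append((sid, run_start, prev))
                run_start = None
            if flag:
                run_start = w
            prev = w
        if run_start is not None:
            segs.append((sid, run_start, prev))
    recs = []
    for sid, w0, w1 in segs:
        a, b = windows[w0], windows[w1]
        recs.append((sid, a.chrom, a.start_cM, b.end_cM, a.start_bp, b.end_bp,
                     b.end_cM - a.start_cM))
    return pd.DataFrame(recs, columns=["sample", "chrom", "start_cM", "end_cM",
                                       "start_bp", "end_bp", "length_cM"])


def summarize_roh(segments: pd.DataFrame, genome_span_cM: float,
                  sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Genome fraction in ROH per size class and the close-kin flag.

    Per sample: fraction of ``genome_span_cM`` covered by segments whose
    length falls in each class of :data:`SIZE_CLASSES`, the total ROH span,
    and ``close_kin`` — true iff any segment is >= 15 cM long.
    """
    if genome_span_cM <= 0:
        raise ValueError("genome_span_cM must be positive")
    if sample_ids is None:
        sample_ids = list(segments["sample"].unique())
    cols = [f"f_{lo:g}_{hi:g}" for lo, hi in SIZE_CLASSES]
    recs = []
    for sid in sample_ids:
        lens = segments.loc[segments["sample"] == sid, "length_cM"].to_numpy()
        fracs = [lens[(lens >= lo) & (lens < hi)].sum() / genome_span_cM
                 for lo, hi in SIZE_CLASSES]
        total = lens.sum() / genome_span_cM
        close_kin = bool(fracs[-1] > 0)
        recs.append([sid, *fracs, total, close_kin])
    return pd.DataFrame(recs, columns=["sample", *cols, "f_total", "close_kin"])
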