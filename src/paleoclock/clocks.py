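"""Generation counters for time-stamped pseudo-haploid genomes.

Two complementary per-genome clocks:

* **Mutation clock** — the derived-mutation density pi_i (derived calls per
  callable bp, relative to the outgroup-polarized ancestral sequence)
  divided by the per-generation mutation rate mu gives G_mut, the number of
  generations separating the genome from the ancestral sequence. A genome
  sampled s generations before present has accumulated s generations fewer
  mutations, so G_mut regressed on sampling time has slope -1.

* **Recombination clock** — for each genome, the probability that a pair of
  same-chromosome SNPs separated by genetic distance d are both derived,
  normalized by the genome's derived fraction over the panel sites. On a
  panel of segregating sites the ancestral reference is the local-tree root,
  whose height r(x) fluctuates along the genome; a genome sampled s
  generations ago carries derived alleles with per-site probability
  proportional to its root-to-sample path t = r - s, so

      P_i(both derived at distance d) = m^2 * [ C(d) + t_i^2 ],

  where m is the per-panel-site mutation scale and C(d) = Cov(r(x), r(y))
  is the root-height autocovariance at distance d — a decay curve shared by
  every genome, because local-root fluctuations are a property of the sample
  set, not of one sample. Dividing by the genome's squared panel derived
  fraction pi_i^panel ~ m * t_i isolates the per-sample signal in the
  *amplitude* of the decay curve:

      N2_i(d) = P_i(d) / (pi_i^panel)^2 = p_i * (1 + C(d) / t_i^2),

  with p_i a nuisance close to 1 absorbing sample-specific depth/error
  effects. Joint weighted least squares (weights = per-bin pair counts)
  over the shared curve C(d) and per-sample (t_i, p_i) identifies every
  t_i up to one global scale factor, which is anchored so that the
  geometric mean of t_i matches the mutation clock's. Older genomes thus
  read out as larger decay amplitudes — shorter root-to-sample paths.

Per-sample uncertainties come from a leave-one-chromosome-out jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .genotypes import SiteMatrix, derived_fraction

__all__ = [
    "ClockConfig",
    "PairDecayCurve",
    "RecClockFit",
    "mutation_clock",
    "pair_statistic",
    "pair_curves",
    "fit_recombination_clock",
    "jackknife_recclock",
]


def _default_bins() -> np.ndarray:
    """40 log-spaced distance-bin edges over 0.1-100 milliMorgans."""
    return np.logspace(np.log10(0.1), np.log10(100.0), 41)


@dataclass(frozen=True)
class ClockConfig:
    """Shared configuration for both clocks.

    ``mu`` is the per-bp per-generation mutation rate on the scale of the
    retained sites (transversion-rescaled in real mode; the simulated rate
    in synthetic mode). ``distance_bins`` are edges in milliMorgans; the
    default range suits deep genealogies, while shallow desk-scale cohorts
    carry their pair signal at shorter ranges (e.g. 0.01-30 mM).
    ``max_pairs_per_bin`` switches the pair statistic from the exact
    all-pairs computation to seeded per-bin subsampling when finite.
    """

    mu: float = 2.3e-8
    masked_chromosomes: frozenset = frozenset()
    distance_bins: np.ndarray = field(default_factory=_default_bins)
    max_pairs_per_bin: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        edges = np.asarray(self.distance_bins, dtype=float)
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be positive and strictly increasing")


def desk_scale_bins() -> np.ndarray:
    """50 log-spaced bins over 0.005-30 mM, for shallow simulated cohorts."""
    return np.logspace(np.log10(0.005), np.log10(30.0), 51)


# ---------------------------------------------------------------------------
# Mutation clock


def mutation_clock(matrix: SiteMatrix, config: ClockConfig) -> pd.DataFrame:
    """Per-sample G_mut = pi_i / mu with leave-one-chromosome-out variance.

    Returns a DataFrame with columns sample, pi, g_mut, var_jk.
    """
    chroms = list(matrix.chrom_lengths)
    recs = []
    for sid in matrix.sample_ids:
        pi = derived_fraction(matrix, sid)
        g = pi / config.mu
        if len(chroms) >= 2:
            loo = np.array([derived_fraction(matrix, sid, exclude_chrom=c) / config.mu
                            for c in chroms])
            m = len(loo)
            var = (m - 1) / m * np.sum((loo - loo.mean()) ** 2)
        else:
            var = np.nan
        recs.append((sid, pi, g, var))
    return pd.DataFrame(recs, columns=["sample", "pi", "g_mut", "var_jk"])


# ---------------------------------------------------------------------------
# Pair statistic


@dataclass
class PairDecayCurve:
    """Binned derived-pair statistic for one sample.

    ``p_both`` is P(both derived | both called) among same-chromosome site
    pairs whose genetic distance falls in each bin; ``n_i`` is that
    probability divided by the sample's panel derived fraction. Bins with
    zero called pairs hold NaN.
    """

    sample: str
    mid_mM: np.ndarray       # geometric bin midpoints, milliMorgans
    n_pairs: np.ndarray      # called pairs per bin for this sample
    p_both: np.ndarray       # P(both derived | both called)
    pi_panel: float          # derived fraction over panel (unmasked) sites
    n_called_sites: float = np.nan  # called panel sites (occupancy weighting)

    @property
    def n_i(self) -> np.ndarray:
        """First-order normalization: P(both derived) / pi_panel."""
        return self.p_both / self.pi_panel

    @property
    def n2_i(self) -> np.ndarray:
        """Second-order normalization P(both derived) / pi_panel^2 (the
        fitted observable; ~1 + C(d)/t_i^2 in expectation)."""
        return self.p_both / self.pi_panel ** 2


def _window_bounds(cm: np.ndarray, lo: float, hi: float):
    """For each site i, the index range [left_i, right_i) of partners j > i
    with cm[j] - cm[i] in [lo, hi)."""
    n = len(cm)
    left = np.searchsorted(cm, cm + lo, side="left")
    right = np.searchsorted(cm, cm + hi, side="left")
    left = np.maximum(left, np.arange(n) + 1)
    right = np.maximum(right, left)
    return left, right


def _accumulate_exact(calls: np.ndarray, cm: np.ndarray, edges_cM: np.ndarray,
                      num: np.ndarray, den: np.ndarray) -> None:
    """Exact all-pairs per-bin counts via windowed prefix sums.

    O(n_bins * n_sites) per sample instead of enumerating pairs: the number
    of (derived, derived) pairs anchored at site i is der_i times the count
    of derived partners in the distance window, which is a difference of
    prefix sums.
    """
    der = (calls == 1).astype(np.float64)
    cal = (calls >= 0).astype(np.float64)
    pref_der = np.concatenate([np.zeros((calls.shape[0], 1)),
                               np.cumsum(der, axis=1)], axis=1)
    pref_cal = np.concatenate([np.zeros((calls.shape[0], 1)),
                               np.cumsum(cal, axis=1)], axis=1)
    for b in range(len(edges_cM) - 1):
        left, right = _window_bounds(cm, edges_cM[b], edges_cM[b + 1])
        num[:, b] += np.sum(der * (pref_der[:, right] - pref_der[:, left]), axis=1)
        den[:, b] += np.sum(cal * (pref_cal[:, right] - pref_cal[:, left]), axis=1)


def _sample_pairs_chrom(cm: np.ndarray, edges_cM: np.ndarray,
                        max_per_bin: int, rng: np.random.Generator):
    """Site-index pairs stratified by distance bin, uniformly subsampled
    without replacement to ``max_per_bin`` per bin."""
    n = len(cm)
    ii, jj, bb = [], [], []
    for b in range(len(edges_cM) - 1):
        left, right = _window_bounds(cm, edges_cM[b], edges_cM[b + 1])
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            continue
        if total <= max_per_bin:
            i_idx = np.repeat(np.arange(n), counts)
            offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
            j_idx = left[i_idx] + offs
        else:
            cum = np.cumsum(counts)
            picks = np.sort(rng.choice(total, size=max_per_bin, replace=False))
            i_idx = np.searchsorted(cum, picks, side="right")
            j_idx = left[i_idx] + (picks - (cum[i_idx] - counts[i_idx]))
        ii.append(i_idx)
        jj.append(j_idx)
        bb.append(np.full(len(i_idx), b, dtype=np.int64))
    if not ii:
        return (np.empty(0, np.int64),) * 3
    return np.concatenate(ii), np.concatenate(jj), np.concatenate(bb)


def _accumulate_subsampled(calls: np.ndarray, cm: np.ndarray,
                           edges_cM: np.ndarray, max_per_bin: int,
                           rng: np.random.Generator,
                           num: np.ndarray, den: np.ndarray) -> None:
    nbins = len(edges_cM) - 1
    n_samples = calls.shape[0]
    i_idx, j_idx, b_idx = _sample_pairs_chrom(cm, edges_cM, max_per_bin, rng)
    if len(i_idx) == 0:
        return
    chunk = max(1, int(2e7) // max(n_samples, 1))
    for lo in range(0, len(i_idx), chunk):
        sl = slice(lo, lo + chunk)
        ci = calls[:, i_idx[sl]]
        cj = calls[:, j_idx[sl]]
        bb = b_idx[sl]
        both_called = (ci >= 0) & (cj >= 0)
        both_der = (ci == 1) & (cj == 1)
        for s in range(n_samples):
            den[s] += np.bincount(bb[both_called[s]], minlength=nbins)
            num[s] += np.bincount(bb[both_der[s]], minlength=nbins)


def pair_curves(matrix: SiteMatrix, gmap: GeneticMap, config: ClockConfig,
                exclude_chrom: str | None = None) -> list[PairDecayCurve]:
    """Binned derived-pair decay curves for every sample.

    Same-chromosome pairs only; chromosomes in ``config.masked_chromosomes``
    (and ``exclude_chrom``, for jackknifing) are excluded. With
    ``max_pairs_per_bin`` None (default) the statistic is computed exactly
    over all pairs via prefix sums; a finite cap enables seeded per-bin
    subsampling instead. The same site pairs serve every genome, so shared
    genealogical fluctuations cancel from between-sample comparisons.
    """
    edges_cM = np.asarray(config.distance_bins, dtype=float) / 10.0
    nbins = len(edges_cM) - 1
    rng = np.random.default_rng(config.seed)
    masked = {str(c) for c in config.masked_chromosomes}
    if exclude_chrom is not None:
        masked.add(str(exclude_chrom))

    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    n_samples = matrix.n_samples

    num = np.zeros((n_samples, nbins))
    den = np.zeros((n_samples, nbins))
    panel_der = np.zeros(n_samples)
    panel_called = np.zeros(n_samples)

    for chrom in matrix.chrom_lengths:
        chrom = str(chrom)
        if chrom in masked:
            continue
        on = np.flatnonzero(chrom_arr == chrom)
        if on.size < 2:
            continue
        cm = np.asarray(gmap.interpolate(chrom, pos_arr[on]), dtype=float)
        order = np.argsort(cm, kind="stable")
        on = on[order]
        cm = cm[order]
        calls = matrix.calls[:, on]
        panel_der += (calls == 1).sum(axis=1)
        panel_called += (calls >= 0).sum(axis=1)
        if config.max_pairs_per_bin is None:
            _accumulate_exact(calls, cm, edges_cM, num, den)
        else:
            _accumulate_subsampled(calls, cm, edges_cM,
                                   config.max_pairs_per_bin, rng, num, den)

    mids_mM = np.sqrt(edges_cM[:-1] * edges_cM[1:]) * 10.0
    curves = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for s, sid in enumerate(matrix.sample_ids):
            p_both = np.where(den[s] > 0, num[s] / np.maximum(den[s], 1), np.nan)
            pi_panel = panel_der[s] / panel_called[s] if panel_called[s] else np.nan
            curves.append(PairDecayCurve(sid, mids_mM, den[s].copy(), p_both,
                                         float(pi_panel), float(panel_called[s])))
    return curves


def pair_statistic(matrix: SiteMatrix, sample: str, gmap: GeneticMap,
                   config: ClockConfig) -> PairDecayCurve:
    """Decay curve for a single sample (see :func:`pair_curves`)."""
    curves = pair_curves(matrix, gmap, config)
    curve = curves[matrix.sample_index(sample)]
    if not np.isfinite(curve.pi_panel) or curve.pi_panel == 0:
        raise ValueError(f"sample {sample!r} has no derived calls; curve undefined")
    return curve


def pair_statistic_bruteforce(matrix: SiteMatrix, sample: str, gmap: GeneticMap,
                              config: ClockConfig) -> PairDecayCurve:
    """Exhaustive double-loop oracle for the binned pair statistic.

    Independent of the vectorized path; quadratic in the number of sites, so
    only usable on small instances.
    """
    edges_cM = np.asarray(config.distance_bins, dtype=float) / 10.0
    nbins = len(edges_cM) - 1
    s = matrix.sample_index(sample)
    masked = {str(c) for c in config.masked_chromosomes}
    num = np.zeros(nbins)
    den = np.zeros(nbins)
    n_der = 0
    n_called = 0
    for chrom in matrix.chrom_lengths:
        chrom = str(chrom)
        if chrom in masked:
            continue
        on = np.flatnonzero(matrix.sites["chrom"].to_numpy() == chrom)
        cm = [float(gmap.interpolate(chrom, p))
              for p in matrix.sites["pos"].to_numpy()[on]]
        calls = matrix.calls[s, on]
        n_der += int((calls == 1).sum())
        n_called += int((calls >= 0).sum())
        for a in range(len(on)):
            for b in range(a + 1, len(on)):
                d = abs(cm[b] - cm[a])
                k = np.searchsorted(edges_cM, d, side="right") - 1
                if k < 0 or d >= edges_cM[-1]:
                    continue
                if calls[a] >= 0 and calls[b] >= 0:
                    den[k] += 1
                    if calls[a] == 1 and calls[b] == 1:
                        num[k] += 1
    mids_mM = np.sqrt(edges_cM[:-1] * edges_cM[1:]) * 10.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p_both = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return PairDecayCurve(matrix.samples["id"].iloc[s], mids_mM, den, p_both,
                          n_der / n_called if n_called else np.nan)


# ---------------------------------------------------------------------------
# Recombination-clock fit


@dataclass
class RecClockFit:
    """Joint least-squares fit of the derived-pair decay model.

    ``T`` is the global scale anchoring relative path lengths to absolute
    generations (geometric-mean match with the mutation clock); ``decay_cM``
    holds the fitted shared root-height covariance profile C(d) per distance
    bin on the anchored scale (generations^2).
    """

    T: float
    t_i: pd.Series           # per sample, generations from root/MRCA to sample
    p_i: pd.Series           # per sample nuisance amplitude (~1)
    rss: float
    converged: bool
    decay_mid_mM: np.ndarray = None
    decay_C: np.ndarray = None
    n_iterations: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.t_i.index, "t_i": self.t_i.values,
                             "p_i": self.p_i.values})


def fit_recombination_clock(curves: list[PairDecayCurve], config: ClockConfig,
                            init: pd.DataFrame | None = None,
                            *, nuisance: str = "none",
                            occupancy_kappa: float = 0.25,
                            max_iter: int = 200,
                            tol: float = 1e-10) -> RecClockFit:
    """Weighted joint fit of the shared decay curve and per-sample (t_i, p_i).

    The observable is N2_i(b) = P(both derived)/pi_i^2 with model
    ``p_i * (1 + C(d_b) * u_i)`` where ``u_i = 1/t_i^2``. The bilinear
    structure is solved by alternating weighted least squares: given C, each
    sample's amplitude is a linear regression; given all samples, each
    C(d_b) is a weighted slope.

    Weights are per-bin called-pair counts deflated for window overlap:
    pairs sharing an anchor site are correlated, so a bin with n pairs over
    m sites carries roughly n / (1 + kappa * n/m) independent units
    (``occupancy_kappa`` controls the deflation).

    ``nuisance`` selects the per-sample amplitude nuisance p_i: ``"none"``
    fixes p_i = 1, appropriate when all genomes were processed identically
    (synthetic cohorts); ``"intercept"`` frees p_i to absorb depth- and
    error-rate-driven amplitude variation in heterogeneous real data.

    The overall scale of C trades off exactly against all t_i; it is
    anchored so the geometric mean of t_i equals the geometric mean of the
    mutation-clock estimates in ``init`` (columns sample, g_mut); without
    ``init`` the geometric mean is anchored at 1,000 generations and only
    relative values are meaningful.
    """
    if nuisance not in ("none", "intercept"):
        raise ValueError("nuisance must be 'none' or 'intercept'")
    valid = [c for c in curves
             if np.isfinite(c.pi_panel) and c.pi_panel > 0
             and np.isfinite(c.p_both).any()]
    if not valid:
        raise ValueError("no valid decay curves to fit")
    S = len(valid)
    Y = np.vstack([c.n2_i for c in valid]) - 1.0
    W = np.vstack([c.n_pairs for c in valid]).astype(float)
    nsites = np.array([c.n_called_sites for c in valid])
    if np.all(np.isfinite(nsites) & (nsites > 0)):
        occ = W / np.maximum(nsites[:, None], 1.0)
        W = W / (1.0 + occupancy_kappa * occ)
    W[~np.isfinite(Y)] = 0.0
    Y = np.nan_to_num(Y)

    # alternating weighted LS on Y = a_i + b_i * v_b  (a = p-1, b = p*u)
    a = np.zeros(S)
    b = np.full(S, 1.0)
    v = np.maximum((W * Y).sum(0) / np.maximum(W.sum(0), 1e-30), 0.0)
    vscale = v.max() if v.max() > 0 else 1.0
    v = v / vscale
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v_old = v
        # shape update: v_b = sum_i w (y - a_i) b_i / sum_i w b_i^2
        v = ((W * (Y - a[:, None]) * b[:, None]).sum(0)
             / np.maximum((W * b[:, None] ** 2).sum(0), 1e-30))
        v = np.maximum(v, 0.0)
        if v.max() > 0:          # fix the gauge inside the iteration
            v = v / v.max()
        if nuisance == "intercept":
            sw = W.sum(1)
            swv = (W * v).sum(1)
            swv2 = (W * v ** 2).sum(1)
            swy = (W * Y).sum(1)
            swvy = (W * Y * v).sum(1)
            det = sw * swv2 - swv ** 2
            ok = det > 0
            b = np.where(ok, (sw * swvy - swv * swy) / np.where(ok, det, 1.0), b)
            a = np.where(sw > 0, (swy - b * swv) / np.maximum(sw, 1e-30), a)
        else:
            b = (W * Y * v).sum(1) / np.maximum((W * v ** 2).sum(1), 1e-30)
        if np.max(np.abs(v - v_old)) < tol:
            converged = True
            break

    p = 1.0 + a
    u = np.maximum(b / np.maximum(p, 1e-12), 1e-12)  # 1/t^2 on the v-gauge
    t_rel = 1.0 / np.sqrt(u)

    if init is not None:
        g = (init.set_index("sample")
             .reindex([c.sample for c in valid])["g_mut"].to_numpy(float))
        g = g[np.isfinite(g) & (g > 0)]
        target = float(np.exp(np.mean(np.log(g)))) if g.size else 1000.0
    else:
        target = 1000.0
    T = target / float(np.exp(np.mean(np.log(t_rel))))
    t = t_rel * T

    resid = Y - (a[:, None] + b[:, None] * v)
    rss = float((W * resid ** 2).sum())
    idx = [c.sample for c in valid]
    return RecClockFit(float(T), pd.Series(t, index=idx), pd.Series(p, index=idx),
                       rss, converged, valid[0].mid_mM, v * T ** 2, it)


def jackknife_recclock(matrix: SiteMatrix, gmap: GeneticMap, config: ClockConfig,
                       init: pd.DataFrame | None = None,
                       **fit_kwargs) -> pd.DataFrame:
    """Leave-one-chromosome-out jackknife variance of t_i.

    Each replicate drops one unmasked chromosome from both the pair curves
    and the mutation-clock anchor, then refits. Returns a DataFrame with
    columns sample, t_i (full-data fit), var_jk.
    """
    chroms = [str(c) for c in matrix.chrom_lengths
              if str(c) not in {str(m) for m in config.masked_chromosomes}]
    if len(chroms) < 2:
        raise ValueError("jackknife needs >=2 unmasked chromosomes")
    if init is None:
        init = mutation_clock(matrix, config)
    full = fit_recombination_clock(pair_curves(matrix, gmap, config), config,
                                   init, **fit_kwargs)
    reps = []
    for c in chroms:
        init_c = pd.DataFrame({
            "sample": matrix.sample_ids,
            "g_mut": [derived_fraction(matrix, s, exclude_chrom=c) / config.mu
                      for s in matrix.sample_ids],
        })
        fit_c = fit_recombination_clock(
            pair_curves(matrix, gmap, config, exclude_chrom=c), config, init_c,
            **fit_kwargs)
        reps.append(fit_c.t_i)
    rep = pd.concat(reps, axis=1)
    m = len(chroms)
    var = ((rep.sub(rep.mean(axis=1), axis=0) ** 2).sum(axis=1)) * (m - 1) / m
    return pd.DataFrame({"sample": full.t_i.index, "t_i": full.t_i.values,
                         "var_jk": var.reindex(full.t_i.index).values})
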