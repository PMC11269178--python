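"""Pseudo-haploid transversion site matrices and the site-filtering pipeline.

The central container is :class:`SiteMatrix`: per-sample, per-site calls in
{0 = ancestral, 1 = derived, -1 = missing}, plus site coordinates/alleles,
per-sample metadata and the callable genome length each sample was assayed
over. The canonical filter order is transversions -> polarization ->
missingness -> adjacent-site thinning; every filter is idempotent and only
ever removes sites.

Coordinates are 1-based inclusive, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_TRANSVERSION_PAIRS = {
    frozenset("AC"), frozenset("AT"), frozenset("GC"), frozenset("GT"),
}


@dataclass
class SiteMatrix:
    """Sample x site call matrix with site and sample annotations.

    Attributes
    ----------
    sites
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based bp, strictly
        increasing within chromosome), ``anc``, ``der`` (single bases).
    calls
        ``int8`` array of shape (n_samples, n_sites); 0 ancestral, 1 derived,
        -1 missing.
    samples
        DataFrame with columns ``id``, ``group``, ``date``, ``depth`` and
        ``call_fraction`` (fraction of the assayed genome callable in this
        sample; 1.0 for fully assayed synthetic data).
    chrom_lengths
        Assayed (callable) length in bp per chromosome, monomorphic sites
        included — the denominator of the per-genome derived fraction.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    samples: pd.DataFrame
    chrom_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape must be (n_samples, n_sites)")
        if "call_fraction" not in self.samples.columns:
            self.samples = self.samples.assign(call_fraction=1.0)
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["id"])

    def sample_index(self, sample: str) -> int:
        idx = np.flatnonzero((self.samples["id"] == sample).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return int(idx[0])

    def callable_length(self, sample: str, exclude_chrom: str | None = None) -> float:
        """Callable bp for one sample, optionally leaving one chromosome out."""
        total = sum(v for c, v in self.chrom_lengths.items()
                    if str(c) != str(exclude_chrom))
        if total <= 0:
            raise ValueError("callable length is not positive")
        frac = float(self.samples["call_fraction"].iloc[self.sample_index(sample)])
        return total * frac

    def take_sites(self, keep: np.ndarray) -> "SiteMatrix":
        keep = np.asarray(keep)
        return replace(self,
                       sites=self.sites.iloc[keep].reset_index(drop=True),
                       calls=self.calls[:, keep])


# ---------------------------------------------------------------------------
# VCF IO


def read_vcf(path, sample_subset: list[str] | None = None, *,
             het_mode: str = "random", seed: int = 0,
             metadata: pd.DataFrame | None = None) -> SiteMatrix:
    """Read a (pseudo-)haploid or diploid VCF into a SiteMatrix.

    Calls are coded against REF (0) / ALT (1); run :func:`polarize` afterwards
    to orient them as ancestral/derived. Diploid heterozygotes are resolved by
    a seeded uniform draw (``het_mode="random"``, mirroring pseudo-
    haploidization) or set to missing (``het_mode="missing"``). Multi-allelic
    sites are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=sample_subset, gts012=True)
    rng = np.random.default_rng(seed)
    rows, cols, dropped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            dropped += 1
            continue
        gts = var.gt_types  # gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        call = np.full(len(gts), MISSING, dtype=np.int8)
        call[gts == 0] = 0
        call[gts == 2] = 1
        if het_mode == "random":
            het = gts == 1
            call[het] = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
        elif het_mode != "missing":
            raise ValueError("het_mode must be 'random' or 'missing'")
        rows.append((str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        cols.append(call)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "anc", "der"])
    calls = (np.array(cols, dtype=np.int8).T if cols
             else np.zeros((len(vcf.samples), 0), dtype=np.int8))
    if metadata is not None:
        samples = metadata.set_index("id").loc[vcf.samples].reset_index()
    else:
        samples = pd.DataFrame({"id": vcf.samples, "group": "NA",
                                "date": np.nan, "depth": np.nan})
    lengths = {str(c): float(l) for c, l in zip(vcf.seqnames, vcf.seqlens or [])}
    if not lengths:
        lengths = {c: float(sub["pos"].max()) for c, sub in sites.groupby("chrom")}
    return SiteMatrix(sites, calls, samples, lengths)


def write_vcf(matrix: SiteMatrix, path) -> None:
    """Write the matrix as a plain-text haploid VCF (anc=REF, der=ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in matrix.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        code = {0: "0", 1: "1", -1: "."}
        for j in range(matrix.n_sites):
            site = matrix.sites.iloc[j]
            gts = "\t".join(code[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.anc}\t{site.der}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filters


def polarize(matrix: SiteMatrix, outgroups: pd.DataFrame, *,
             require_all: bool = False) -> SiteMatrix:
    """Orient alleles as ancestral/derived from an outgroup panel.

    ``outgroups`` has columns chrom, pos and one column per outgroup lineage
    (missing alleles as '.', 'N' or NaN). A site is polarizable when all
    non-missing outgroups agree (all three must be present if
    ``require_all``), and the agreed allele matches one of the two site
    alleles; calls are swapped where the agreed allele is the current 'der'.
    All other sites are dropped.
    """
    og_cols = [c for c in outgroups.columns if c not in ("chrom", "pos")]
    panel = outgroups.set_index(["chrom", "pos"])
    keep, swap = [], []
    for j, site in enumerate(matrix.sites.itertuples(index=False)):
        try:
            row = panel.loc[(site.chrom, site.pos)]
        except KeyError:
            continue
        alleles = [str(row[c]).upper() for c in og_cols]
        called = [a for a in alleles if a in "ACGT"]
        if not called or len(set(called)) != 1:
            continue
        if require_all and len(called) != len(og_cols):
            continue
        anc = called[0]
        if anc == site.anc:
            keep.append(j); swap.append(False)
        elif anc == site.der:
            keep.append(j); swap.append(True)
        # ancestral allele not among the site's alleles -> drop
    out = matrix.take_sites(np.array(keep, dtype=int))
    swap = np.array(swap, dtype=bool)
    if swap.any():
        calls = out.calls.copy()
        sub = calls[:, swap]
        flipped = np.where(sub == MISSING, MISSING, 1 - sub).astype(np.int8)
        calls[:, swap] = flipped
        sites = out.sites.copy()
        anc = sites["anc"].to_numpy().copy()
        der = sites["der"].to_numpy().copy()
        anc[swap], der[swap] = der[swap], anc[swap]
        sites["anc"], sites["der"] = anc, der
        out = replace(out, sites=sites, calls=calls)
    return out


def filter_transversions(matrix: SiteMatrix) -> SiteMatrix:
    """Keep only transversion substitutions (A<->C, A<->T, G<->C, G<->T)."""
    keep = np.array([frozenset((a, d)) in _TRANSVERSION_PAIRS
                     for a, d in zip(matrix.sites["anc"], matrix.sites["der"])])
    return matrix.take_sites(np.flatnonzero(keep))


def filter_missingness(matrix: SiteMatrix, max_missing: float = 0.30) -> SiteMatrix:
    """Drop sites missing in ``max_missing`` or more of the samples.

    The boundary is inclusive: with 10 samples and max_missing 0.30, a site
    with 3 missing calls is dropped.
    """
    if not 0 < max_missing <= 1:
        raise ValueError("max_missing must be in (0, 1]")
    na_frac = (matrix.calls == MISSING).mean(axis=0)
    return matrix.take_sites(np.flatnonzero(na_frac < max_missing))


def thin_adjacent(matrix: SiteMatrix, seed: int = 0) -> SiteMatrix:
    """Keep one random site per run of adjacent (consecutive-bp) sites.

    Emulates the retention of a single transversion where two or more
    successive transversions occupy adjacent genomic positions.
    """
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    n = len(pos)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and chroms[k + 1] == chroms[j] and pos[k + 1] == pos[k] + 1:
            k += 1
        keep.append(int(rng.integers(j, k + 1)) if k > j else j)
        j = k + 1
    return matrix.take_sites(np.array(keep, dtype=int))


def pseudo_haploid_call(n_ancestral: int, n_derived: int, *,
                        min_reads: int = 2,
                        rng: np.random.Generator | None = None) -> int:
    """Single-read draw from allele read counts; missing below ``min_reads``.

    Returns 0 (ancestral), 1 (derived) or -1 (missing). Base-quality
    filtering of the counts is assumed upstream.
    """
    if n_ancestral < 0 or n_derived < 0:
        raise ValueError("read counts must be non-negative")
    total = n_ancestral + n_derived
    if total < min_reads:
        return int(MISSING)
    rng = rng if rng is not None else np.random.default_rng()
    return int(rng.integers(0, total) >= n_ancestral)


def downsample_calls(matrix: SiteMatrix, keep_prob: float, seed: int = 0) -> SiteMatrix:
    """Per-call allele dropout: each call kept independently with ``keep_prob``.

    Emulates coverage downsampling at the call level; the per-sample callable
    fraction and depth proxy are rescaled by ``keep_prob`` so that the derived
    fraction stays unbiased.
    """
    if not 0 < keep_prob <= 1:
        raise ValueError("keep_prob must be in (0, 1]")
    if keep_prob == 1.0:
        return matrix
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.calls.shape) >= keep_prob
    calls = matrix.calls.copy()
    calls[mask] = MISSING
    samples = matrix.samples.copy()
    samples["call_fraction"] = samples["call_fraction"] * keep_prob
    samples["depth"] = samples["depth"] * keep_prob
    return replace(matrix, calls=calls, samples=samples)


def derived_fraction(matrix: SiteMatrix, sample: str,
                     exclude_chrom: str | None = None) -> float:
    """Per-genome derived-mutation density pi_i = derived calls / callable bp.

    Missing calls do not enter the numerator; the denominator is the assayed
    callable length (monomorphic sites included), not the SNP-panel size.
    """
    i = matrix.sample_index(sample)
    row = matrix.calls[i]
    if exclude_chrom is not None:
        on = (matrix.sites["chrom"].to_numpy() != str(exclude_chrom))
        row = row[on]
    return float((row == 1).sum()) / matrix.callable_length(sample, exclude_chrom)
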