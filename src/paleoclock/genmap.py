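"""Genetic-map interpolation, genetic distances, and fixed-size cM windows.

A :class:`GeneticMap` holds monotone physical->genetic anchors per chromosome
(bp strictly increasing, cM non-decreasing). Queries are linearly interpolated
between bracketing anchors; positions outside the anchored range are clamped
to the terminal cM value, so off-map sites fall into the terminal windows
rather than inventing recombination beyond the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "Window", "make_windows"]


@dataclass(frozen=True)
class Window:
    """Half-open genetic window [start_cM, end_cM) with bp projections."""

    chrom: str
    start_cM: float
    end_cM: float
    start_bp: float
    end_bp: float

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


class GeneticMap:
    """Per-chromosome piecewise-linear bp -> cM map."""

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValueError(f"chromosome {chrom}: need >=2 anchors")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"chromosome {chrom}: bp anchors must strictly increase")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM anchors must be non-decreasing")
            self._anchors[str(chrom)] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    @classmethod
    def uniform(cls, chrom_lengths: dict[str, float], cM_per_Mb: float = 1.0) -> "GeneticMap":
        """Uniform-rate map (1 cM/Mb corresponds to r = 1e-8 per bp)."""
        anchors = {
            str(c): (np.array([1.0, float(length)]),
                     np.array([0.0, (float(length) - 1.0) * cM_per_Mb / 1e6]))
            for c, length in chrom_lengths.items()
        }
        return cls(anchors)

    @classmethod
    def read_plink_map(cls, path) -> "GeneticMap":
        """Read a PLINK ``.map``-style file: chrom, id, cM, bp (whitespace-separated)."""
        df = pd.read_csv(path, sep=r"\s+", header=None,
                         names=["chrom", "id", "cM", "bp"], dtype={"chrom": str})
        return cls._from_frame(df[["chrom", "bp", "cM"]])

    @classmethod
    def read_two_column(cls, path, chrom: str | None = None) -> "GeneticMap":
        """Read a (bp, cM) two-column dialect, or (chrom, bp, cM) three-column."""
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if df.shape[1] == 2:
            df.columns = ["bp", "cM"]
            df["chrom"] = chrom if chrom is not None else "1"
        else:
            df.columns = ["chrom", "bp", "cM"]
        df["chrom"] = df["chrom"].astype(str)
        return cls._from_frame(df[["chrom", "bp", "cM"]])

    @classmethod
    def _from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        anchors = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("bp")
            anchors[str(chrom)] = (sub["bp"].to_numpy(float), sub["cM"].to_numpy(float))
        return cls(anchors)

    def interpolate(self, chrom: str, bp) -> np.ndarray | float:
        """cM position(s) at physical coordinate(s) ``bp`` (clamped at map ends)."""
        try:
            xs, ys = self._anchors[str(chrom)]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in map") from None
        # np.interp clamps to terminal y values outside [xs[0], xs[-1]]
        return np.interp(bp, xs, ys)

    def distance(self, chrom_a: str, bp_a, chrom_b: str, bp_b) -> float:
        """Genetic distance in cM between two sites on the same chromosome."""
        if str(chrom_a) != str(chrom_b):
            raise ValueError("genetic distance is undefined across chromosomes")
        return float(abs(self.interpolate(chrom_a, bp_a) - self.interpolate(chrom_a, bp_b)))

    def bp_at(self, chrom: str, cm) -> np.ndarray | float:
        """Approximate inverse: physical position(s) at genetic coordinate(s)."""
        xs, ys = self._anchors[str(chrom)]
        return np.interp(cm, ys, xs)

    def span_cM(self, chrom: str) -> float:
        xs, ys = self._anchors[str(chrom)]
        return float(ys[-1] - ys[0])

    def total_span_cM(self) -> float:
        return float(sum(self.span_cM(c) for c in self._anchors))

    def start_cM(self, chrom: str) -> float:
        return float(self._anchors[str(chrom)][1][0])


def make_windows(gmap: GeneticMap, size_cM: float = 1.0) -> list[Window]:
    """Tile each mapped chromosome with half-open windows of ``size_cM``.

    Windows are anchored at the chromosome's first mapped cM position and tile
    the mapped span without gaps or overlap; the last window may be shorter.
    """
    if size_cM <= 0:
        raise ValueError("window size must be positive")
    windows: list[Window] = []
    for chrom in gmap.chromosomes:
        lo = gmap.start_cM(chrom)
        hi = lo + gmap.span_cM(chrom)
        start = lo
        while start < hi:
            end = min(start + size_cM, hi)
            windows.append(Window(chrom, start, end,
                                  float(gmap.bp_at(chrom, start)),
                                  float(gmap.bp_at(chrom, end))))
            start += size_cM
    return windows


def assign_windows(gmap: GeneticMap, windows: list[Window], chrom: str,
                   bp: np.ndarray) -> np.ndarray:
    """Index into ``windows`` for each site; -1 when no window contains it.

    The terminal window is treated as closed on the right so that the last
    mapped position (and clamped off-map positions) belongs to it.
    """
    cm = np.atleast_1d(np.asarray(gmap.interpolate(chrom, bp), dtype=float))
    idx = np.full(cm.shape, -1, dtype=np.int64)
    per_chrom = [(i, w) for i, w in enumerate(windows) if w.chrom == str(chrom)]
    if not per_chrom:
        return idx
    starts = np.array([w.start_cM for _, w in per_chrom])
    ids = np.array([i for i, _ in per_chrom])
    last_end = per_chrom[-1][1].end_cM
    pos = np.searchsorted(starts, cm, side="right") - 1
    ok = (pos >= 0) & (cm <= last_end)
    idx[ok] = ids[pos[ok]]
    return idx
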