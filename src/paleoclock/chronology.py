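"""Calendar arithmetic between generation counts and calendar years BCE/CE.

Dates are held internally as signed astronomical years (BCE year Y maps to -Y)
on a continuous axis; the historical absence of year 0 is ignored, which is
inert for the prehistoric (all-BCE) dates this package deals with. Display
rounding is to the nearest year; internal arithmetic keeps full precision.
"""

from __future__ import annotations

__all__ = [
    "date_before",
    "generations_between",
    "gen_time_from_fold",
    "bce_to_year",
    "year_to_bce",
    "calbp_to_bce",
]


def bce_to_year(bce: float) -> float:
    """Signed astronomical year for a BCE year label (2200 bce -> -2200)."""
    return -float(bce)


def year_to_bce(year: float) -> float:
    """BCE year label for a signed astronomical year (-2200 -> 2200 bce)."""
    return -float(year)


def calbp_to_bce(calbp: float) -> float:
    """Convert calibrated years before 1950 to a BCE year label."""
    return float(calbp) - 1950.0


def date_before(anchor_bce: float, n_generations: float, gen_time_years: float) -> int:
    """Date ``n_generations`` before an anchor, as a BCE year.

    Counting backwards in time increases the BCE label, so the result is
    ``anchor_bce + n_generations * gen_time_years`` rounded to the nearest
    year. Example: 80 generations of 8 years before 3500 bce is 4140 bce.

    Parameters
    ----------
    anchor_bce
        Anchor date, years BCE.
    n_generations
        Number of generations to step back (must be >= 0).
    gen_time_years
        Average generation time in years (must be > 0).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    if gen_time_years <= 0:
        raise ValueError("gen_time_years must be positive")
    return round(anchor_bce + n_generations * gen_time_years)


def generations_between(date_a_bce: float, date_b_bce: float, gen_time_years: float) -> float:
    """Number of generations separating two BCE dates at a given generation time."""
    if gen_time_years <= 0:
        raise ValueError("gen_time_years must be positive")
    return abs(date_a_bce - date_b_bce) / gen_time_years


def gen_time_from_fold(average_years: float, fold_change: float) -> float:
    """Generation time implied by a fold-acceleration of an average.

    A ``fold_change``-fold acceleration of an ``average_years`` generation
    time yields ``average_years / fold_change``, rounded to one decimal for
    reporting (7.4 yr accelerated 2.1-fold -> 3.5 yr).
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    return round(average_years / fold_change, 1)
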