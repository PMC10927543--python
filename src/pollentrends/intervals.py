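"""Fixed 500-year binning grid for pollen assemblage time series.

Ages are in calibrated years before present (cal yr BP, present = 1950 CE);
larger values are older and negative ages are post-1950.  The analysis grid
is ten 500-year intervals tiling (4,900, -100] cal yr BP.  Intervals are
half-open, old-exclusive / young-inclusive: a sample falls in the interval
whose young bound it sits on (4,400 BP belongs to (4,900, 4,400], while
4,399.9 belongs to (4,400, 3,900]).  The grid extremes are special: a
sample at exactly 4,900 BP is kept in the earliest interval, and ages at
or below -100 BP fall outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TimeInterval", "default_intervals", "OLDEST_BOUND", "YOUNGEST_BOUND"]

OLDEST_BOUND = 4_900.0
YOUNGEST_BOUND = -100.0
INTERVAL_WIDTH = 500.0


@dataclass(frozen=True, order=True)
class TimeInterval:
    """One 500-year bin ``(old, young]`` in cal yr BP.

    ``index`` runs 1..10 from the oldest interval (4,900-4,400) to the most
    recent (400 cal yr BP to the present).
    """

    old: float
    young: float
    index: int

    def __post_init__(self) -> None:
        if not (self.old > self.young):
            raise ValueError(f"old bound must exceed young bound: {self}")
        if abs((self.old - self.young) - INTERVAL_WIDTH) > 1e-9:
            raise ValueError(f"interval must span {INTERVAL_WIDTH} years: {self}")

    @property
    def midpoint(self) -> float:
        """Midpoint age, used as the regressor for trend slopes."""
        return 0.5 * (self.old + self.young)

    def contains(self, age: float) -> bool:
        """Young-inclusive membership; the grid handles its own extremes."""
        return self.young <= age < self.old

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.old:g}, {self.young:g}] cal yr BP"


def default_intervals() -> list[TimeInterval]:
    """The ten-interval grid (4,900, 4,400], ..., (400, -100], oldest first."""
    out = []
    old = OLDEST_BOUND
    for i in range(10):
        out.append(TimeInterval(old=old, young=old - INTERVAL_WIDTH, index=i + 1))
        old -= INTERVAL_WIDTH
    assert out[-1].young == YOUNGEST_BOUND
    return out


def interval_for_age(age: float, intervals: list[TimeInterval] | None = None) -> TimeInterval | None:
    """Return the interval containing ``age``, or None if out of range.

    In range means ``youngest bound < age <= oldest bound``: a sample at
    the oldest bound belongs to the earliest interval; one at the youngest
    bound is outside the grid.
    """
    intervals = intervals or default_intervals()
    oldest = max(iv.old for iv in intervals)
    youngest = min(iv.young for iv in intervals)
    if age <= youngest:
        return None
    if age == oldest:
        return min(intervals, key=lambda iv: iv.index)
    for iv in intervals:
        if iv.contains(age):
            return iv
    return None
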