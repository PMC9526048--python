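"""Core containers shared across the pipeline.

All genomic coordinates are 0-based, end-exclusive, so that the length of an
interval is always ``end - start``.  Recombination rates are carried either as
the population-scaled rate rho (= 4*Ne*r) per bp, or, after conversion, in
cM/Mb.  Missing values in windowed tracks are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Units a WindowedTrack may carry.
UNITS = ("rho/bp", "cM/Mb", "pi", "proportion", "depth", "log-units")

#: Closed vocabulary of pairwise population comparisons.
COMPARISON_LABELS = ("C vs W", "C vs T", "W vs T")


class RhoscapeError(ValueError):
    """Base class for validation failures anywhere in the pipeline."""


@dataclass(frozen=True)
class IntervalRateMap:
    """Piecewise-constant recombination map for one chromosome arm.

    Intervals are ordered, non-overlapping ``[start, end)`` pairs, each with a
    constant rho/bp.  This mirrors the text output of LD-based rate
    estimators, where adjacent SNP positions delimit the constant pieces.
    """

    arm: str
    population: str
    starts: np.ndarray
    ends: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "rho", rho)
        if not (len(starts) == len(ends) == len(rho)):
            raise RhoscapeError("starts, ends and rho must have equal length")
        if len(starts) == 0:
            raise RhoscapeError(f"{self.arm}: interval map is empty")
        if np.any(ends <= starts):
            i = int(np.argmax(ends <= starts))
            raise RhoscapeError(
                f"{self.arm}: interval {i} has end <= start "
                f"({int(starts[i])}..{int(ends[i])})"
            )
        if np.any(np.diff(starts) < 0):
            raise RhoscapeError(f"{self.arm}: intervals are not sorted by start")
        if np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise RhoscapeError(
                f"{self.arm}: intervals {i} and {i + 1} overlap"
            )
        if np.any(rho < 0):
            raise RhoscapeError(f"{self.arm}: negative rho value")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def span(self) -> tuple[int, int]:
        """Covered span (first start, last end)."""
        return int(self.starts[0]), int(self.ends[-1])

    def total_bp(self) -> int:
        return int(self.lengths.sum())


@dataclass
class WindowedTrack:
    """Fixed-width window means of one quantity along one arm.

    ``values[k]`` covers ``[start_offset + k*window_bp,
    start_offset + (k+1)*window_bp)``; NaN marks windows with no data.
    """

    arm: str
    window_bp: int
    values: np.ndarray
    units: str
    start_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.window_bp <= 0:
            raise RhoscapeError("window_bp must be positive")
        if self.values.ndim != 1 or len(self.values) < 1:
            raise RhoscapeError("values must be a non-empty 1-D array")
        if self.units not in UNITS:
            raise RhoscapeError(
                f"unknown units {self.units!r}; expected one of {UNITS}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def window_starts(self) -> np.ndarray:
        return self.start_offset + self.window_bp * np.arange(len(self.values))

    def with_values(self, values: np.ndarray, units: str | None = None) -> "WindowedTrack":
        return WindowedTrack(
            arm=self.arm,
            window_bp=self.window_bp,
            values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
            start_offset=self.start_offset,
        )


@dataclass(frozen=True)
class DivergentRegionSet:
    """Sorted intervals flagged as divergent for one pairwise comparison."""

    comparison: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.comparison not in COMPARISON_LABELS:
            raise RhoscapeError(
                f"unknown comparison label {self.comparison!r}; "
                f"allowed labels: {', '.join(COMPARISON_LABELS)}"
            )
        ivs = tuple(sorted((int(a), int(b)) for a, b in self.intervals))
        for a, b in ivs:
            if b <= a:
                raise RhoscapeError(
                    f"{self.comparison}: interval ({a}, {b}) has end <= start"
                )
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneAnnotation:
    """Gene and exon spans for one or more arms, 0-based end-exclusive."""

    genes: list[tuple[str, str, int, int]] = field(default_factory=list)
    exons: list[tuple[str, int, int]] = field(default_factory=list)

    def genes_on(self, arm: str) -> list[tuple[str, int, int]]:
        out = [(n, s, e) for (n, a, s, e) in self.genes if a == arm]
        out.sort(key=lambda g: (g[1], g[2]))
        return out

    def exons_on(self, arm: str) -> list[tuple[int, int]]:
        out = [(s, e) for (a, s, e) in self.exons if a == arm]
        out.sort()
        return out


@dataclass
class WarmSpot:
    """A localized region of strongly elevated recombination.

    ``fold`` is the spot's mean rho over the chromosome-arm background; spots
    are restricted to 0.5-7 kb, far broader and weaker than mammalian
    hotspots, hence "warm".
    """

    arm: str
    start: int
    end: int
    mean_rho: float
    fold: float
    genes: list[str] = field(default_factory=list)
    divergent_overlaps: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def genes_label(self) -> str:
        return ", ".join(self.genes) if self.genes else "Intergenic"

    def divergent_label(self) -> str:
        return ", ".join(self.divergent_overlaps) if self.divergent_overlaps else "None"


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting half-open intervals into a sorted disjoint set."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


__all__ = [
    "UNITS",
    "COMPARISON_LABELS",
    "RhoscapeError",
    "IntervalRateMap",
    "WindowedTrack",
    "DivergentRegionSet",
    "GeneAnnotation",
    "WarmSpot",
    "merge_intervals",
    "replace",
]
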