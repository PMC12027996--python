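"""Z-score range construction and the fusion/rivalry range classifier.

The discrimination procedure at the heart of the package:

1. pool one indicator's values within a paradigm (both states together;
   the two fusion control groups count as one fusion pool) and z-score
   them against the pool mean and SD;
2. summarise each state as a normalized Mean +- SD interval;
3. excise the overlap between the fusion and rivalry intervals (the
   excised region becomes an abstention zone);
4. intersect the per-paradigm intervals of a state across paradigms,
   greedily dropping a paradigm whose (direction-inverted) interval
   empties the intersection, and report the merged interval as
   midpoint +- half-width;
5. classify a new z-value by closed-interval membership: inside exactly
   one state's interval -> that state, otherwise indeterminate.

All reported values are rounded half-away-from-zero to 3 decimals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

STATES = ("fusion", "rivalry")


def round3(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (table convention)."""
    if not np.isfinite(x):
        return x
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5 + 1e-9), x) / scale


@dataclass(frozen=True)
class Interval:
    """Closed interval; ``lower > upper`` encodes the empty interval."""

    lower: float
    upper: float

    @classmethod
    def empty(cls) -> "Interval":
        return cls(np.inf, -np.inf)

    @property
    def is_empty(self) -> bool:
        return self.lower > self.upper

    @property
    def width(self) -> float:
        return 0.0 if self.is_empty else self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2.0

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0

    def contains(self, x: float) -> bool:
        return (not self.is_empty) and self.lower <= x <= self.upper

    def intersect(self, other: "Interval") -> "Interval":
        lo = max(self.lower, other.lower)
        hi = min(self.upper, other.upper)
        return Interval(lo, hi) if lo <= hi else Interval.empty()


@dataclass
class ZScorePool:
    """Normalization pool for one indicator within one paradigm."""

    paradigm: str
    indicator: str
    mean: float
    sd: float
    n_fusion: int = 0
    n_rivalry: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("pool SD must be positive")

    @classmethod
    def fit(cls, values, paradigm: str = "", indicator: str = "",
            n_fusion: int = 0, n_rivalry: int = 0) -> "ZScorePool":
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ValueError("need at least 2 values to fit a pool")
        return cls(paradigm, indicator, float(arr.mean()),
                   float(arr.std(ddof=1)), n_fusion, n_rivalry)


def zscore(values, pool: ZScorePool) -> np.ndarray:
    """(x - pool mean) / pool SD."""
    return (np.asarray(values, dtype=float) - pool.mean) / pool.sd


@dataclass
class StateRange:
    """Normalized Mean +- SD summary of one state's z-values."""

    state: str
    mean: float
    sd: float

    @property
    def lower(self) -> float:
        return self.mean - self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.sd

    @property
    def interval(self) -> Interval:
        return Interval(self.lower, self.upper)

    @classmethod
    def from_interval(cls, state: str, interval: Interval) -> "StateRange":
        return cls(state, interval.midpoint, interval.half_width)


def state_range(z_values, state: str) -> StateRange:
    """Mean and sample SD of one state's z-values as a StateRange."""
    arr = np.asarray(z_values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 values for a state range")
    return StateRange(state, float(arr.mean()), float(arr.std(ddof=1)))


@dataclass
class OverlapResult:
    fusion: Interval
    rivalry: Interval
    abstain: Interval
    flags: list[str] = field(default_factory=list)


def remove_overlap(fusion: Interval, rivalry: Interval) -> OverlapResult:
    """Excise the mutual overlap from both state intervals.

    The intersection becomes the abstention zone.  Disjoint inputs (or a
    single shared boundary point) pass through unchanged.  When one
    interval contains the other, the inner interval empties (flagged) and
    the outer keeps its larger remaining piece (flagged as split).
    """
    shared = fusion.intersect(rivalry)
    if shared.is_empty or shared.width == 0.0:
        return OverlapResult(fusion, rivalry, Interval.empty())
    flags = []
    out = {}
    for name, iv in (("fusion", fusion), ("rivalry", rivalry)):
        pieces = []
        if iv.lower < shared.lower:
            pieces.append(Interval(iv.lower, shared.lower))
        if iv.upper > shared.upper:
            pieces.append(Interval(shared.upper, iv.upper))
        if not pieces:
            out[name] = Interval.empty()
            flags.append(f"{name} emptied by overlap removal")
        elif len(pieces) == 1:
            out[name] = pieces[0]
        else:
            out[name] = max(pieces, key=lambda p: p.width)
            flags.append(f"{name} split by containment; larger piece kept")
    return OverlapResult(out["fusion"], out["rivalry"], shared, flags)


def intersect_ranges(intervals: Sequence[Interval]) -> Interval:
    """[max of lowers, min of uppers]; empty when they do not meet."""
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    out = intervals[0]
    for iv in intervals[1:]:
        out = out.intersect(iv)
    return out


@dataclass
class MergedRange:
    """Cross-paradigm merged interval for one indicator and state."""

    indicator: str
    state: str
    interval: Interval
    included_paradigms: tuple[str, ...]
    dropped_paradigms: tuple[str, ...] = ()

    @property
    def midpoint(self) -> float:
        return self.interval.midpoint

    @property
    def half_width(self) -> float:
        return self.interval.half_width


def merge_across_paradigms(intervals: Mapping[str, Interval], state: str,
                           directions: Mapping[str, float] | None = None,
                           indicator: str = "") -> MergedRange:
    """Intersect one state's intervals across paradigms.

    If the full intersection is empty, paradigms are dropped greedily,
    preferring paradigms whose fusion-minus-rivalry effect direction
    opposes the majority (``directions`` maps paradigm -> signed effect).
    Candidate subsets are tried largest-first, fewest-inverted-first; the
    first subset of >= 2 paradigms with a non-empty intersection wins.
    """
    names = sorted(intervals)
    if len(names) < 2:
        raise ValueError("need ranges from at least 2 paradigms")
    directions = directions or {}
    signs = {p: np.sign(directions.get(p, 0.0)) for p in names}
    majority = np.sign(sum(signs.values())) or 1.0
    inverted = {p for p in names if signs[p] and signs[p] != majority}

    def sort_key(subset: tuple[str, ...]):
        return (-len(subset), len(set(subset) & inverted), subset)

    subsets = [c for k in range(len(names), 1, -1)
               for c in itertools.combinations(names, k)]
    for subset in sorted(subsets, key=sort_key):
        merged = intersect_ranges([intervals[p] for p in subset])
        if not merged.is_empty:
            dropped = tuple(p for p in names if p not in subset)
            return MergedRange(indicator, state, merged, subset, dropped)
    raise ValueError("no >=2-paradigm subset has a non-empty intersection")


def classify(z: float, fusion: Interval, rivalry: Interval) -> str:
    """Closed-interval membership call: fusion / rivalry / indeterminate.

    The supplied intervals must not overlap beyond a shared endpoint
    (run :func:`remove_overlap` first); a z touching a shared endpoint is
    indeterminate.
    """
    shared = fusion.intersect(rivalry)
    if not shared.is_empty and shared.width > 0:
        raise ValueError("state intervals overlap; remove overlap first")
    in_f, in_r = fusion.contains(z), rivalry.contains(z)
    if in_f and in_r:
        return "indeterminate"
    if in_f:
        return "fusion"
    if in_r:
        return "rivalry"
    return "indeterminate"


class RangeDiscriminator(BaseEstimator, ClassifierMixin):
    """Range-based fusion/rivalry classifier for a single indicator.

    ``fit`` pools the indicator values (both states), z-scores them, builds
    per-state Mean +- SD intervals and removes their overlap; ``predict``
    maps new values to ``{"fusion", "rivalry", "indeterminate"}``.

    Parameters
    ----------
    trim_overlap : bool
        Excise the fusion/rivalry overlap after range construction.

    Attributes
    ----------
    pool_mean_, pool_sd_ : float
        Normalization pool moments.
    fusion_range_, rivalry_range_ : StateRange
        Raw per-state ranges before overlap removal.
    fusion_interval_, rivalry_interval_, abstain_ : Interval
        Operating intervals after overlap removal.
    """

    def __init__(self, trim_overlap: bool = True):
        self.trim_overlap = trim_overlap

    def fit(self, X, y) -> "RangeDiscriminator":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        labels = self._as_labels(y)
        mask = np.isfinite(x)
        x, labels = x[mask], labels[mask]
        pool = ZScorePool.fit(x, n_fusion=int((labels == "fusion").sum()),
                              n_rivalry=int((labels == "rivalry").sum()))
        self.pool_mean_, self.pool_sd_ = pool.mean, pool.sd
        z = zscore(x, pool)
        self.fusion_range_ = state_range(z[labels == "fusion"], "fusion")
        self.rivalry_range_ = state_range(z[labels == "rivalry"], "rivalry")
        if self.trim_overlap:
            res = remove_overlap(self.fusion_range_.interval,
                                 self.rivalry_range_.interval)
            self.fusion_interval_ = res.fusion
            self.rivalry_interval_ = res.rivalry
            self.abstain_ = res.abstain
            self.flags_ = list(res.flags)
        else:
            self.fusion_interval_ = self.fusion_range_.interval
            self.rivalry_interval_ = self.rivalry_range_.interval
            self.abstain_ = Interval.empty()
            self.flags_ = []
        self.classes_ = np.array(["fusion", "rivalry"])
        return self

    @classmethod
    def from_intervals(cls, fusion: Interval, rivalry: Interval,
                       pool_mean: float = 0.0,
                       pool_sd: float = 1.0) -> "RangeDiscriminator":
        """Build a fitted discriminator from externally supplied intervals
        (e.g. cross-paradigm merged ranges)."""
        est = cls()
        shared = fusion.intersect(rivalry)
        if not shared.is_empty and shared.width > 0:
            raise ValueError("supplied intervals overlap")
        est.pool_mean_, est.pool_sd_ = pool_mean, pool_sd
        est.fusion_range_ = StateRange.from_interval("fusion", fusion)
        est.rivalry_range_ = StateRange.from_interval("rivalry", rivalry)
        est.fusion_interval_ = fusion
        est.rivalry_interval_ = rivalry
        est.abstain_ = Interval.empty()
        est.flags_ = []
        est.classes_ = np.array(["fusion", "rivalry"])
        return est

    @staticmethod
    def _as_labels(y: np.ndarray) -> np.ndarray:
        if y.dtype.kind in "ifub":
            return np.where(np.asarray(y, dtype=float) > 0.5,
                            "rivalry", "fusion")
        return y.astype(str)

    def _z(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        return (x - self.pool_mean_) / self.pool_sd_

    def predict(self, X) -> np.ndarray:
        z = self._z(X)
        return np.array([classify(v, self.fusion_interval_,
                                  self.rivalry_interval_) for v in z])

    def determinate_accuracy(self, X, y) -> tuple[float, float]:
        """(accuracy over determinate calls, abstention fraction)."""
        pred = self.predict(X)
        truth = self._as_labels(np.asarray(y))
        det = pred != "indeterminate"
        abstain_frac = float(1.0 - det.mean()) if len(pred) else 0.0
        if det.sum() == 0:
            return np.nan, abstain_frac
        return float((pred[det] == truth[det]).mean()), abstain_frac


# ---------------------------------------------------------------------------
# Table-style reports

def range_report(rows: Sequence[dict], path: str | Path | None = None,
                 ) -> pd.DataFrame:
    """Normalize range rows (Table-1/Table-2 style) and optionally write TSV.

    Expected row keys: paradigm (or "merged"), indicator, state, mean, sd,
    lower, upper, included_paradigms.
    """
    df = pd.DataFrame(rows, columns=["paradigm", "indicator", "state",
                                     "mean", "sd", "lower", "upper",
                                     "included_paradigms"])
    for col in ("mean", "sd", "lower", "upper"):
        df[col] = df[col].map(lambda v: round3(float(v)))
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
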