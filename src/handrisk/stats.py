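"""Descriptive analyses of hand-hygiene behaviour.

Chains of missed opportunities, unique-room histograms, per-room daily
unwashed time, the distribution of time spent outside a room before a
non-compliant entrance, and the Spearman rank correlation used to compare
PER with (100 − ECR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exposure import EntranceRecord, MetricsResult


@dataclass(frozen=True)
class RankCorrelation:
    """Spearman coefficient with sample size and p-value.

    The coefficient is the Pearson correlation of average-rank vectors (ties
    get average ranks); the p-value uses the large-sample t approximation
    with n − 2 degrees of freedom.  A constant input leaves the coefficient
    undefined (NaN), never a sentinel number.
    """

    coefficient: float
    n: int
    p_value: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.coefficient)


def spearman(x: Sequence[float], y: Sequence[float]) -> RankCorrelation:
    """Spearman rank correlation between two equal-length vectors (n ≥ 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RankCorrelation(math.nan, n, math.nan)
    res = sps.spearmanr(x, y)
    return RankCorrelation(float(res.statistic), n, float(res.pvalue))


@dataclass(frozen=True)
class ChainSummary:
    """Per-entrance chain records plus the headline fractions.

    ``frac_chain_ge2``: among non-compliant entrances, the fraction preceded
    by at least one further missed opportunity since the last wash (chain
    length ≥ 2).  ``frac_same_room_repeat``: the fraction whose chain, while
    of length ≥ 2, stayed within a single room (consecutive visits to the
    same room).  Both are NaN when there are no non-compliant entrances.
    """

    records: pd.DataFrame
    n_noncompliant: int
    frac_chain_ge2: float
    frac_same_room_repeat: float


def chain_analysis(entrances: Sequence[EntranceRecord] | MetricsResult) -> ChainSummary:
    """Extract missed-opportunity chains from entrance audit records.

    A chain is the maximal run of missed crossings by one worker since their
    last wash; a wash (equivalently, any compliant crossing) terminates it.
    The chain length recorded at a non-compliant entrance counts that
    entrance itself.
    """
    if isinstance(entrances, MetricsResult):
        entrances = entrances.entrances
    rows = [
        {
            "staff_id": e.staff_id,
            "room_id": e.room_id,
            "entrance_time": e.t_en,
            "chain_length": e.n_missed_before,
            "unique_rooms_in_chain": e.n_unique_rooms,
            "minutes_outside_since_wash": e.minutes_outside_since_wash,
        }
        for e in entrances
        if not e.compliant
    ]
    records = pd.DataFrame(
        rows,
        columns=[
            "staff_id", "room_id", "entrance_time", "chain_length",
            "unique_rooms_in_chain", "minutes_outside_since_wash",
        ],
    )
    n = len(records)
    if n == 0:
        return ChainSummary(records, 0, math.nan, math.nan)
    ge2 = records["chain_length"] >= 2
    same_room = ge2 & (records["unique_rooms_in_chain"] == 1)
    return ChainSummary(records, n, float(ge2.mean()), float(same_room.mean()))


def unique_rooms_histogram(chains: ChainSummary | pd.DataFrame) -> pd.Series:
    """Percentage histogram of unique rooms per chain (bins 1..max observed)."""
    records = chains.records if isinstance(chains, ChainSummary) else chains
    if len(records) == 0:
        return pd.Series(dtype=float, name="percent")
    counts = records["unique_rooms_in_chain"].value_counts()
    bins = np.arange(1, int(counts.index.max()) + 1)
    counts = counts.reindex(bins, fill_value=0).sort_index()
    pct = 100.0 * counts / counts.sum()
    pct.name = "percent"
    pct.index.name = "unique_rooms"
    return pct


def unwashed_room_time_daily(
    metrics: MetricsResult | pd.DataFrame, n_days: int | None = None
) -> pd.Series:
    """Average unwashed in-room minutes per room per 24 h.

    Total unwashed in-room time per room divided by the number of days in the
    observation period (default: the number of distinct days present in the
    data; a room with no entrances on some day still divides by the full
    period).
    """
    if isinstance(metrics, MetricsResult):
        df = pd.DataFrame(
            [
                {"room_id": e.room_id, "day": e.day, "unwashed_in_room": e.unwashed_in_room}
                for e in metrics.entrances
            ],
            columns=["room_id", "day", "unwashed_in_room"],
        )
    else:
        df = metrics
    if len(df) == 0:
        return pd.Series(dtype=float, name="unwashed_minutes_per_day")
    if n_days is None:
        n_days = df["day"].nunique()
    out = df.groupby("room_id")["unwashed_in_room"].sum() / float(n_days)
    out.name = "unwashed_minutes_per_day"
    return out


def time_outside_distribution(
    entrances: Sequence[EntranceRecord] | ChainSummary | pd.DataFrame,
    bin_width: float = 5.0,
) -> pd.Series:
    """Binned distribution of minutes outside since last wash, non-compliant
    entrances only; fractions sum to 1.  Default bin width: 5 minutes."""
    if isinstance(entrances, ChainSummary):
        values = entrances.records["minutes_outside_since_wash"].to_numpy()
    elif isinstance(entrances, pd.DataFrame):
        values = entrances["minutes_outside_since_wash"].to_numpy()
    else:
        values = np.array(
            [e.minutes_outside_since_wash for e in entrances if not e.compliant]
        )
    if len(values) == 0:
        return pd.Series(dtype=float, name="fraction")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = float(np.max(values))
    n_bins = max(1, int(math.floor(top / bin_width)) + 1)
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    index = pd.IntervalIndex.from_breaks(edges, closed="left")
    frac = pd.Series(counts / counts.sum(), index=index, name="fraction")
    frac.index.name = "minutes_outside"
    return frac
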