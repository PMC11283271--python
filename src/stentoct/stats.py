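"""Grouping and significance machinery for CDisp comparisons.

Measurements are grouped either per day (inter-day reproducibility) or
pooled across days per location (regional effect of the implant), then
compared pairwise with two-sided independent-samples t-tests.  Welch's
unequal-variance test is the default, with a pooled-variance switch; no
multiplicity correction is applied by default (a Holm option exists).
Significance stars follow the conventional cutoffs 0.05 / 0.01 /
0.001 / 0.0001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motion import CDispRecord

__all__ = [
    "GroupedCDisp",
    "PairwiseTestResult",
    "StatsError",
    "star_code",
    "bin_records",
    "pairwise_ttests",
    "summarize_groups",
    "records_to_frame",
    "frame_to_records",
]

KNOWN_LOCATIONS = ("upper stent", "lower stent", "between", "remote")
STAR_CUTOFFS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


class StatsError(ValueError):
    """Raised for malformed grouping inputs."""


def star_code(p_value: float) -> str:
    """Significance stars: <0.05 '*', <0.01 '**', <0.001 '***', <0.0001 '****'."""
    if not (0.0 <= p_value <= 1.0):
        raise StatsError(f"p-value {p_value} outside [0, 1]")
    for cutoff, stars in STAR_CUTOFFS:
        if p_value < cutoff:
            return stars
    return "ns"


@dataclass
class GroupedCDisp:
    """CDisp values binned into cells keyed (eye, location[, day])."""

    groups: dict[tuple, list[float]]
    scheme: str

    def sizes(self) -> dict[tuple, int]:
        return {k: len(v) for k, v in self.groups.items()}


@dataclass
class PairwiseTestResult:
    """Two-sided independent-samples t-test between two cells."""

    label_a: tuple
    label_b: tuple
    t_statistic: float
    p_value: float
    n1: int
    n2: int
    star: str = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError("p-value outside [0, 1]")
        self.star = star_code(self.p_value)


def _normalize_location(label: str) -> str:
    lab = label.strip().lower().replace("-", " ").replace("_", " ")
    # Stent-adjacent sites above/below a given stent pool into that
    # stent's group; all remote sites pool together.
    for loc in KNOWN_LOCATIONS:
        if lab.startswith(loc) or lab.replace(" above", "").replace(" below", "") == loc:
            return loc
    raise StatsError(f"unknown location label {label!r}")


def bin_records(records: list[CDispRecord], scheme: str = "by_location") -> GroupedCDisp:
    """Bin CDisp records per day or pooled by location.

    ``by_day`` keeps one cell per (eye, location, day) to probe
    inter-day reproducibility; ``by_location`` pools all days (and all
    sites of each location group) into one cell per (eye, location).
    """
    if scheme not in ("by_day", "by_location"):
        raise StatsError(f"unknown binning scheme {scheme!r}")
    groups: dict[tuple, list[float]] = {}
    for rec in records:
        if rec.location_label == "":
            raise StatsError("record missing location label")
        loc = _normalize_location(rec.location_label)
        if scheme == "by_day":
            if rec.day_label == "":
                raise StatsError("record missing day label for by_day binning")
            key = (rec.eye, loc, rec.day_label)
        else:
            key = (rec.eye, loc)
        groups.setdefault(key, []).append(float(rec.cdisp_um))
    return GroupedCDisp(groups=groups, scheme=scheme)


def independent_ttest(
    a, b, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs >= 2 values for a t-test")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pairwise_ttests(
    grouped: GroupedCDisp,
    equal_var: bool = False,
    holm: bool = False,
) -> list[PairwiseTestResult]:
    """All pairwise comparisons between cells that differ in one key only.

    In ``by_day`` grouping this yields inter-day comparisons within each
    (eye, location); in ``by_location`` grouping, between-location
    comparisons within each eye.  ``holm=True`` applies a Holm step-down
    adjustment (off by default; the conventional display uses raw
    pairwise p-values).
    """
    keys = sorted(grouped.groups)
    results: list[PairwiseTestResult] = []
    for ka, kb in itertools.combinations(keys, 2):
        if sum(x != y for x, y in zip(ka, kb)) != 1:
            continue
        a, b = grouped.groups[ka], grouped.groups[kb]
        t, p = independent_ttest(a, b, equal_var=equal_var)
        results.append(
            PairwiseTestResult(
                label_a=ka, label_b=kb, t_statistic=t, p_value=p, n1=len(a), n2=len(b)
            )
        )
    if holm and results:
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        prev = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p_value)
            adj = max(adj, prev)
            prev = adj
            results[idx].p_value = adj
            results[idx].star = star_code(adj)
    return results


def summarize_groups(grouped: GroupedCDisp) -> pd.DataFrame:
    """Per-cell mean, sample SD, quartiles and extremes.

    Matches the conventional display: bar height = mean, error bar =
    sample standard deviation; box = first/third quartiles (linear
    interpolation), whiskers = min/max.  A single-value cell has an
    undefined SD (NaN, flagged) and quartiles equal to the value.
    """
    rows = []
    for key, values in sorted(grouped.groups.items()):
        if len(values) == 0:
            raise StatsError(f"empty cell {key}")
        v = np.asarray(values, dtype=float)
        rows.append(
            {
                "cell": " / ".join(str(k) for k in key),
                "n": v.size,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                "sd_defined": v.size > 1,
                "q1": np.percentile(v, 25),
                "median": np.percentile(v, 50),
                "q3": np.percentile(v, 75),
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[CDispRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cdisp_um": [r.cdisp_um for r in records],
            "eye": [r.eye for r in records],
            "location": [r.location_label for r in records],
            "day": [r.day_label for r in records],
            "replicate": [r.replicate_index for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[CDispRecord]:
    records = []
    for _, row in frame.iterrows():
        rep = row.get("replicate")
        records.append(
            CDispRecord(
                cdisp_um=float(row["cdisp_um"]),
                eye=str(row.get("eye", "")),
                location_label=str(row.get("location", "")),
                day_label=str(row.get("day", "")),
                replicate_index=None if rep is None or pd.isna(rep) else int(rep),
            )
        )
    return records
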