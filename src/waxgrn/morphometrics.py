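"""Internode morphometrics and wax composition summaries.

An internode is modelled as the lateral walls of two intersecting truncated
cones whose largest diameters sit at the internode ends, giving

    SA = (h/2)(D_top + D_mid)(pi/2) + (h/2)(D_mid + D_base)(pi/2)

in cm^2 (with equal diameters this reduces to the cylinder wall pi*d*h).
Wax load is the summed mass of the hexane washes per unit surface area
(ug/cm^2). GC-MS composition is summarized as each component class's share
of the total peak area (%TIC), with Welch t-tests against a reference
phytomer group (stars at p < 0.01 '*' and p < 0.001 '**').
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InternodeMeasurement",
    "WaxExtraction",
    "WAX_CLASSES",
    "internode_surface_area",
    "wax_load",
    "composition_percent_tic",
    "composition_group_test",
    "significance_stars",
]

WAX_CLASSES = ("alcohol", "aldehyde", "alkane", "ester", "other")


@dataclass(frozen=True)
class InternodeMeasurement:
    """Caliper measurements of one internode, in cm."""

    length: float
    diameter_top: float
    diameter_middle: float
    diameter_base: float
    phytomer: str = ""

    def __post_init__(self) -> None:
        for name in ("length", "diameter_top", "diameter_middle", "diameter_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WaxExtraction:
    """Summed hexane-wash masses (ug) over a measured surface area (cm^2)."""

    wash_masses: tuple[float, ...]
    surface_area: float
    organ: str = ""

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.wash_masses):
            raise ValueError("wash masses must be nonnegative")
        if self.surface_area <= 0:
            raise ValueError("surface area must be positive")


def internode_surface_area(m: InternodeMeasurement | None = None, **kwargs) -> float:
    """Two-truncated-cone lateral surface area of an internode (cm^2)."""
    if m is None:
        m = InternodeMeasurement(**kwargs)
    h = m.length
    return (h / 2.0) * (m.diameter_top + m.diameter_middle) * math.pi / 2.0 + \
           (h / 2.0) * (m.diameter_middle + m.diameter_base) * math.pi / 2.0


def wax_load(x: WaxExtraction) -> float:
    """Total extracted wax mass per unit surface area (ug/cm^2)."""
    return sum(x.wash_masses) / x.surface_area


def composition_percent_tic(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-sample wax-class shares of total peak area (%TIC).

    ``peaks`` needs columns sample, group, wax_class, area (a chain_length
    column is permitted and ignored). Returns one row per sample with the
    phytomer group and one percentage column per class; rows sum to 100.
    """
    required = {"sample", "group", "wax_class", "area"}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing column(s): {sorted(missing)}")
    bad = set(peaks["wax_class"]) - set(WAX_CLASSES)
    if bad:
        raise ValueError(f"unknown wax class(es): {sorted(bad)}")
    if (peaks["area"] < 0).any():
        raise ValueError("peak areas must be nonnegative")

    totals = peaks.groupby("sample")["area"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total peak area for sample(s): {list(zero.index)}")

    by_class = (
        peaks.pivot_table(index="sample", columns="wax_class", values="area",
                          aggfunc="sum", fill_value=0.0)
        .reindex(columns=WAX_CLASSES, fill_value=0.0)
    )
    pct = 100.0 * by_class.div(totals, axis=0)
    groups = peaks.drop_duplicates("sample").set_index("sample")["group"]
    pct.insert(0, "group", groups.loc[pct.index])
    return pct


def composition_group_stats(percent: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of class percentages per phytomer group."""
    value_cols = [c for c in percent.columns if c != "group"]
    stats_df = percent.groupby("group")[value_cols].agg(["mean", "std"])
    return stats_df


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.01:
        return "*"
    return ""


def composition_group_test(
    percent: pd.DataFrame, reference_group: str = "P1-7"
) -> pd.DataFrame:
    """Welch t-tests of class percentages for each group vs the reference.

    Returns rows (wax_class, group, p, stars); every compared group needs at
    least two samples.
    """
    if reference_group not in set(percent["group"]):
        raise ValueError(f"reference group {reference_group!r} absent from table")
    counts = percent.groupby("group").size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with <2 samples: {list(small.index)}")

    value_cols = [c for c in percent.columns if c != "group"]
    ref = percent[percent["group"] == reference_group]
    rows = []
    for group in sorted(set(percent["group"]) - {reference_group}):
        other = percent[percent["group"] == group]
        for cls in value_cols:
            a = ref[cls].to_numpy(dtype=float)
            b = other[cls].to_numpy(dtype=float)
            if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and np.allclose(a.mean(), b.mean()):
                p = 1.0
            else:
                p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
            rows.append((cls, group, p, significance_stars(p)))
    return pd.DataFrame(rows, columns=["wax_class", "group", "p", "stars"])
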