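"""Sample-level association statistics for diversification cohorts.

Slide-level present/absent calls are crossed with clinical or molecular
labels in 2x2 contingency tables and tested with Fisher's exact test;
continuous per-slide quantities are compared with Kruskal–Wallis; and
slides are assigned microenvironmental subtypes (Lymphocyte-high /
Stromal-high / Other) from their lymphocyte and stromal percentages.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = factor level (positive / other),
    columns = diversification (present / absent)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(
    table: ContingencyTable2x2 | np.ndarray, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns the sample odds ratio a*d/(b*c) (``inf`` when b*c = 0 with
    a*d > 0, ``nan`` when a margin is zero) and the exact hypergeometric
    p-value; the two-sided p sums all tables with fixed margins whose
    probability does not exceed the observed table's
    (minimum-likelihood convention).  A zero row or column margin makes
    the test degenerate: p = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
        if arr.shape != (2, 2):
            raise ValueError("need a 2x2 table")
        ContingencyTable2x2(*arr.ravel().tolist())  # validate
    a, b, c, d = arr.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        return math.nan, 1.0
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
    if alternative not in alt:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.fisher_exact(arr, alternative=alt[alternative])
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis rank test with tie correction.

    Accepts two or more collections; returns (H, p) with p from the
    chi-squared approximation on k-1 degrees of freedom.  All-identical
    values are a degenerate but legal input: H = 0, p = 1.
    """
    if len(groups) == 1:
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in cleaned):
        raise ValueError("every group must be non-empty")
    if sum(len(g) for g in cleaned) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = stats.kruskal(*cleaned)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class MicroenvSubtype:
    slide_id: str
    lymphocyte_pct: float
    stromal_pct: float
    label: str  # "Lymphocyte-high" | "Stromal-high" | "Other"


def microenv_subtype(
    lymphocyte_pct,
    stromal_pct,
    slide_ids=None,
    mode: str = "percentile",
    hi: float = 75.0,
    lo: float = 25.0,
) -> list[MicroenvSubtype]:
    """Assign microenvironmental subtypes from per-slide composition.

    Lymphocyte-high: lymphocyte abundance at/above the high threshold AND
    stromal abundance at/below the low threshold; Stromal-high is the
    mirror image; everything else is Other.  In ``percentile`` mode
    (default) the thresholds are the cohort's 75th/25th percentiles of the
    respective percentages — the cohort-calibrated reading of the
    75%/25% rule; ``absolute`` mode applies ``hi``/``lo`` as raw
    percentages.
    """
    lym = np.asarray(lymphocyte_pct, dtype=float)
    strm = np.asarray(stromal_pct, dtype=float)
    if lym.shape != strm.shape:
        raise ValueError("lymphocyte and stromal arrays must be aligned")
    if slide_ids is None:
        slide_ids = [f"slide{i}" for i in range(len(lym))]
    if mode == "percentile":
        if len(lym) < 4:
            raise ValueError("percentile mode needs a cohort of >= 4 slides")
        lym_hi, lym_lo = np.percentile(lym, [hi, lo])
        str_hi, str_lo = np.percentile(strm, [hi, lo])
    elif mode == "absolute":
        if not (0 <= lo <= 100 and 0 <= hi <= 100):
            raise ValueError("absolute thresholds must be in [0, 100]")
        lym_hi = str_hi = hi
        lym_lo = str_lo = lo
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for sid, l, s in zip(slide_ids, lym, strm):
        if l >= lym_hi and s <= str_lo:
            label = "Lymphocyte-high"
        elif s >= str_hi and l <= lym_lo:
            label = "Stromal-high"
        else:
            label = "Other"
        out.append(MicroenvSubtype(sid, float(l), float(s), label))
    return out


def build_contingency(
    summaries: pd.DataFrame,
    labels: pd.Series,
    positive_level,
) -> ContingencyTable2x2:
    """Cross slide-level present/absent calls with a categorical label.

    ``summaries`` needs columns ``slide_id`` and ``present``; ``labels`` is
    indexed by slide_id.  Slides with a missing label (NaN/None — the
    "Unknown" convention) are dropped entirely.  Cell layout:
    a = positive & present, b = other & present, c = positive & absent,
    d = other & absent.
    """
    summ = summaries.set_index("slide_id") if "slide_id" in summaries.columns \
        else summaries
    common = summ.index.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no overlapping slide ids between summaries and labels")
    lab = labels.loc[common]
    keep = lab.notna()
    lab = lab[keep]
    present = summ.loc[lab.index, "present"].astype(bool)
    pos = lab == positive_level
    return ContingencyTable2x2(
        a=int((pos & present).sum()),
        b=int((~pos & present).sum()),
        c=int((pos & ~present).sum()),
        d=int((~pos & ~present).sum()),
    )
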