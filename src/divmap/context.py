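"""Microenvironmental context of diversification zones.

Given a fitted zone map and its diversification flags, these routines
quantify zonal composition (cancer / lymphocyte / stromal fractions),
partition zones into the ordered groups *diversified* < *adjacent* <
*rest*, test ordered trends with the Jonckheere–Terpstra statistic, and
correlate zone-level marker scores (e.g. galectin-3 positivity) with other
zonal quantities under the 30–70% tumor-content filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CellTable
from .tessellation import WeightsGraph, ZoneMap

GROUP_DIVERSIFIED, GROUP_ADJACENT, GROUP_REST = 1, 2, 3


def zone_composition(zone_map: ZoneMap, table: CellTable) -> pd.DataFrame:
    """Per-zone class counts and fractions.

    Returns a frame indexed by zone_id with columns n_cancer,
    n_lymphocyte, n_stromal, n_total and the corresponding fractions
    (tumor_fraction, lymphocyte_fraction, stromal_fraction), plus
    marker_mean when the table carries per-cell marker values.
    """
    df = table.data
    zone = pd.Series(zone_map.assignment, index=df.index, name="zone_id")
    counts = (
        df.groupby([zone, "cell_class"], observed=False).size()
        .unstack(fill_value=0)
        .reindex(range(zone_map.m), fill_value=0)
    )
    out = pd.DataFrame(index=pd.RangeIndex(zone_map.m, name="zone_id"))
    for cls in ("cancer", "lymphocyte", "stromal"):
        out[f"n_{cls}"] = counts.get(cls, pd.Series(0, index=counts.index))
    out["n_total"] = out[["n_cancer", "n_lymphocyte", "n_stromal"]].sum(axis=1)
    with np.errstate(invalid="ignore"):
        denom = out["n_total"].replace(0, np.nan)
        out["tumor_fraction"] = out["n_cancer"] / denom
        out["lymphocyte_fraction"] = out["n_lymphocyte"] / denom
        out["stromal_fraction"] = out["n_stromal"] / denom
    if table.has_marker:
        out["marker_mean"] = df.groupby(zone)["marker_value"].mean().reindex(
            range(zone_map.m))
    return out


def zonal_groups(flags: pd.Series, weights: WeightsGraph) -> pd.Series:
    """Partition zones into diversified (1) / adjacent (2) / rest (3).

    ``adjacent`` means not flagged itself but sharing a queen-contiguity
    edge with at least one flagged zone; flagged zones keep group 1 even
    when they neighbor other flagged zones.
    """
    flags = flags.astype(bool)
    groups = pd.Series(GROUP_REST, index=flags.index, name="group")
    groups[flags] = GROUP_DIVERSIFIED
    flagged = set(flags.index[flags])
    for zid in flags.index:
        if flags[zid]:
            continue
        if zid in weights.graph and flagged.intersection(weights.graph.neighbors(zid)):
            groups[zid] = GROUP_ADJACENT
    return groups


def _jt_statistic(samples: list[np.ndarray]) -> float:
    """Jonckheere–Terpstra J with ties counted one-half."""
    j = 0.0
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            xa = samples[a][:, None]
            xb = samples[b][None, :]
            j += np.sum(xa < xb) + 0.5 * np.sum(xa == xb)
    return float(j)


def jonckheere_test(
    values,
    groups,
    method: str = "normal_approx",
    alternative: str = "increasing",
    rng_seed: int = 0,
    n_permutations: int = 9999,
) -> tuple[float, float]:
    """Jonckheere–Terpstra trend test across ordered groups.

    J sums, over every ordered pair of groups, the Mann–Whitney count of
    value pairs ordered with the group labels (ties count 1/2).
    ``alternative="increasing"`` rejects for large J (values rise along the
    group order), ``"decreasing"`` for small J — e.g. lymphocyte abundance
    falling toward the diversified group when groups are ordered
    diversified < adjacent < rest... use "increasing"; ordered the other
    way, "decreasing".

    ``method="normal_approx"`` uses the tie-corrected normal approximation;
    ``"permutation"`` estimates the null by label permutation with the
    add-one (Hope) correction.

    Returns ``(J, p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must be aligned")
    levels = np.unique(groups)
    samples = [values[groups == g] for g in levels]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty ordered groups")
    j_obs = _jt_statistic(samples)
    if alternative not in ("increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")

    if method == "normal_approx":
        p = _jt_normal_p(values, samples, j_obs, alternative)
    elif method == "permutation":
        rng = np.random.default_rng(rng_seed)
        sizes = [len(s) for s in samples]
        pooled = np.concatenate(samples)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts, at = [], 0
            for sz in sizes:
                parts.append(perm[at:at + sz])
                at += sz
            j_star = _jt_statistic(parts)
            if alternative == "increasing":
                count += j_star >= j_obs
            else:
                count += j_star <= j_obs
        p = (1.0 + count) / (1.0 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return j_obs, float(p)


def _jt_normal_p(values, samples, j_obs, alternative) -> float:
    """Tie-corrected normal approximation for the J null distribution."""
    sizes = np.array([len(s) for s in samples], dtype=float)
    n = sizes.sum()
    _, tie_counts = np.unique(values, return_counts=True)
    t = tie_counts.astype(float)
    mean_j = (n**2 - np.sum(sizes**2)) / 4.0
    term1 = (n * (n - 1) * (2 * n + 5)
             - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(sizes * (sizes - 1) * (sizes - 2))
             * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * n * (n - 1) * (n - 2)))
    term3 = (np.sum(sizes * (sizes - 1)) * np.sum(t * (t - 1))
             / (8.0 * n * (n - 1)))
    var_j = term1 + term2 + term3
    if var_j <= 0:
        return 1.0
    z = (j_obs - mean_j) / np.sqrt(var_j)
    if alternative == "increasing":
        return float(stats.norm.sf(z))
    return float(stats.norm.cdf(z))


def zone_marker_correlation(
    values_a,
    values_b,
    composition: pd.DataFrame,
    tumor_fraction_range: tuple[float, float] = (0.30, 0.70),
) -> tuple[float, int]:
    """Spearman correlation between two zonal quantities on mixed zones.

    Zones are filtered to tumor_fraction within ``tumor_fraction_range``
    (inclusive bounds) before correlating, so the estimate comes from
    zones where cancer and microenvironment genuinely co-occur.

    Returns ``(rho, n_zones_used)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    tf = composition["tumor_fraction"].to_numpy(dtype=float)
    if not (len(a) == len(b) == len(tf)):
        raise ValueError("values and composition must cover the same zones")
    lo, hi = tumor_fraction_range
    keep = (tf >= lo) & (tf <= hi) & np.isfinite(a) & np.isfinite(b)
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError(
            f"only {n_used} zones survive the tumor-fraction filter; need >= 3"
        )
    rho = stats.spearmanr(a[keep], b[keep]).statistic
    return float(rho), n_used
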