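"""Local Moran's I on zonal shape variability, with analytic and
Monte-Carlo significance.

The statistic for zone *i* is the unnormalized local Moran form

    I_i = (Y_i - Ybar) * sum_j w_ij (Y_j - Ybar)

computed on the zonal shape-variability values Y over the binary
queen-contiguity weights w.  Significance is assessed against the
conditional-randomization null: Y_i is held fixed while the remaining
values are permuted over the remaining zones.  For binary weights the
first two moments of I_i under that null have exact closed forms
(sampling without replacement of the focal zone's neighbor values), giving
the z-score route; the Hope Monte-Carlo route estimates the same null by
explicit permutation with the add-one correction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tessellation import WeightsGraph


def shape_factor(perimeter, area):
    """Nuclear shape factor p / (2 * sqrt(pi * a)): inverse circularity.

    Equals 1 for a perfect circle (isoperimetric equality) and grows as the
    outline becomes more irregular for the same area.  Inputs in µm / µm²;
    the result is dimensionless.  Vectorized over array inputs.
    """
    p = np.asarray(perimeter, dtype=float)
    a = np.asarray(area, dtype=float)
    if np.any(p <= 0) or np.any(a <= 0):
        raise ValueError("perimeter and area must be positive")
    out = p / (2.0 * np.sqrt(np.pi * a))
    return float(out) if out.ndim == 0 else out


def _neighbor_lists(w: WeightsGraph, order: list) -> list[np.ndarray]:
    pos = {z: i for i, z in enumerate(order)}
    return [
        np.array(sorted(pos[j] for j in w.neighbors(z) if j in pos), dtype=int)
        for z in order
    ]


def local_morans_i(
    y: np.ndarray, w: WeightsGraph, mean_mode: str = "global", order=None
) -> np.ndarray:
    """Local Moran's I for every zone.

    Parameters
    ----------
    y : array of zonal values, aligned with ``order`` (default: sorted nodes
        of ``w``).
    mean_mode : {"global", "neighborhood"}
        Reference mean Ybar: the global mean of y (default, the Anselin
        form) or, per zone, the mean of y over that zone's neighbors.
    Zones with no neighbors get I = 0.
    """
    order = list(w.nodes if order is None else order)
    y = np.asarray(y, dtype=float)
    if len(y) != len(order):
        raise ValueError("y and zone order length mismatch")
    nbrs = _neighbor_lists(w, order)
    if mean_mode == "global":
        ybar_i = np.full(len(y), y.mean())
        ybar_j = ybar_i
    elif mean_mode == "neighborhood":
        ybar_i = np.array([y[nb].mean() if len(nb) else y[i]
                           for i, nb in enumerate(nbrs)])
        ybar_j = ybar_i
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    out = np.zeros(len(y))
    for i, nb in enumerate(nbrs):
        if len(nb) == 0:
            continue
        out[i] = (y[i] - ybar_i[i]) * np.sum(y[nb] - ybar_j[i])
    return out


def analytic_moments(
    y: np.ndarray, w: WeightsGraph, order=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional-randomization mean, variance and z-score of local I.

    Holding z_i = Y_i - Ybar fixed and permuting the other n-1 deviations
    over the other zones, the neighbor sum for a zone with w_i binary
    neighbors is a without-replacement sample of w_i values, so

        E[I_i]   = -w_i * z_i**2 / (n - 1)
        Var[I_i] = z_i**2 * w_i * s2 * (n - 1 - w_i) / (n - 2)

    with s2 the population variance of the held-out deviations.  Global
    mean mode only.  Zones with Var = 0 (isolated zone, z_i = 0, or all
    other values equal) get z = NaN.

    Returns
    -------
    (E_I, Var_I, z) arrays aligned with ``order``.
    """
    order = list(w.nodes if order is None else order)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 zones for the randomization moments")
    z = y - y.mean()
    deg = np.array([w.degree(zone) for zone in order], dtype=float)
    e_i = -deg * z**2 / (n - 1)
    # population variance of the n-1 deviations excluding the focal one
    sum_z = z.sum()  # 0 up to round-off
    sum_z2 = np.sum(z**2)
    mu_rest = (sum_z - z) / (n - 1)
    var_rest = (sum_z2 - z**2) / (n - 1) - mu_rest**2
    var_rest = np.clip(var_rest, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_i = z**2 * deg * var_rest * (n - 1 - deg) / (n - 2)
        var_i = np.clip(var_i, 0.0, None)
        i_obs = local_morans_i(y, w, "global", order)
        zscore = np.where(var_i > 0, (i_obs - e_i) / np.sqrt(var_i), np.nan)
    return e_i, var_i, zscore


def analytic_pvalues(zscore: np.ndarray, tail: str = "two_sided") -> np.ndarray:
    """Normal-theory p-values from the standardized local Moran z-scores."""
    zscore = np.asarray(zscore, dtype=float)
    if tail == "two_sided":
        return 2.0 * stats.norm.sf(np.abs(zscore))
    if tail == "upper":
        return stats.norm.sf(zscore)
    raise ValueError(f"unknown tail {tail!r}")


def permutation_null(
    y: np.ndarray,
    w: WeightsGraph,
    n_permutations: int = 999,
    rng_seed: int = 0,
    tail: str = "two_sided",
    order=None,
) -> np.ndarray:
    """Hope-style conditional-permutation p-values for local Moran's I.

    For each zone the remaining values are permuted ``n_permutations``
    times; the p-value uses the add-one correction
    ``p = (1 + #extreme) / (1 + n_permutations)`` so it is bounded below by
    ``1/(1+n_permutations)``.  Two-sided extremeness is |I*| >= |I_obs|.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    order = list(w.nodes if order is None else order)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(rng_seed)
    nbrs = _neighbor_lists(w, order)
    zdev = y - y.mean()
    i_obs = local_morans_i(y, w, "global", order)
    pvals = np.ones(n)
    for i, nb in enumerate(nbrs):
        wi = len(nb)
        if wi == 0:
            continue
        rest = np.delete(zdev, i)
        # each permutation only needs which w_i of the n-1 values land on
        # the neighbors: batched sampling without replacement via random keys
        draws = np.empty(n_permutations)
        batch = max(1, int(5_000_000 / max(n - 1, 1)))
        for lo in range(0, n_permutations, batch):
            hi = min(lo + batch, n_permutations)
            keys = rng.random((hi - lo, n - 1))
            take = np.argpartition(keys, wi - 1, axis=1)[:, :wi]
            draws[lo:hi] = rest[take].sum(axis=1)
        i_star = zdev[i] * draws
        if tail == "two_sided":
            extreme = np.abs(i_star) >= np.abs(i_obs[i])
        elif tail == "upper":
            extreme = i_star >= i_obs[i]
        else:
            raise ValueError(f"unknown tail {tail!r}")
        pvals[i] = (1.0 + extreme.sum()) / (1.0 + n_permutations)
    return pvals


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
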