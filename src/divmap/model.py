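"""Detection of morphological diversification zones.

The model: a tumor section, represented as a per-cell table, is partitioned
into Voronoi zones seeded by randomly chosen cancer cells.  Each zone is
scored by Y_i, the standard deviation of the nuclear shape factor
p / (2*sqrt(pi*a)) over its cancer cells.  Zones where Y is locally,
significantly elevated — judged by local Moran's I on the queen-contiguity
zone graph, standardized against the conditional-randomization null and
FDR-adjusted within the slide — are flagged as *diversification zones*.
A slide is called "present" when it has at least one such zone.

The public surface follows the statsmodels convention:

>>> model = DiversificationModel(table, params)          # doctest: +SKIP
>>> res = model.fit(rng_seed=17)                         # doctest: +SKIP
>>> res.summary()                                        # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd

from . import moran, tessellation
from .io import CellTable
from .tessellation import WeightsGraph, ZoneMap

__all__ = [
    "DiversificationParams",
    "TessellationConfig",
    "SlideSummary",
    "DiversificationModel",
    "DiversificationResults",
    "zone_variability",
    "flag_diversified",
    "summarize_sample",
    "run_pipeline",
]


@dataclasses.dataclass
class TessellationConfig:
    """How the slide is partitioned before testing.

    ``area_unit_scale`` (µm² per area unit) rescales the tissue area before
    the square-root seed-count rule.  The default of 10 makes the
    desk-scale synthetic slide (5x5 mm) yield ~527 zones — the cohort
    average zones-per-tumor of the full-scale analysis — so the synthetic
    slide is a scale replica of a typical tumor section in both zone count
    and (proportionally) cells per zone.
    """

    area_unit_scale: float = 10.0
    tissue_method: str = "convex_hull"
    alpha: Optional[float] = None
    target_class: str = "cancer"
    n_seeds: Optional[int] = None  # override the area rule when set


@dataclasses.dataclass
class DiversificationParams:
    """Tuning knobs of the zonal diversification test.

    min_cancer_cells_per_zone : zones with fewer target-class cells are
        excluded from the spatial test (an SD needs >= 2 values).
    mean_mode : reference mean in local Moran's I — "global" (default) or
        "neighborhood" (mean over each zone's neighbors).
    method : "analytic" z-score p-values (default), "permutation" for the
        Hope Monte-Carlo p, or "both" to compute the two side by side
        (flags then use the analytic p).
    alpha, fdr_method : significance level after Benjamini–Hochberg
        adjustment across the slide's zones.
    tail : "two_sided" (default) or "upper".
    flag_rule : "significant_and_high" (default) additionally requires
        Y_i above the slide's global mean, so flagged zones are always
        high-variability zones; "significant_any" flags on q alone.
    """

    min_cancer_cells_per_zone: int = 2
    mean_mode: str = "global"
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    tail: str = "two_sided"
    flag_rule: str = "significant_and_high"
    method: str = "analytic"
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cancer_cells_per_zone < 2:
            raise ValueError("min_cancer_cells_per_zone must be >= 2")
        if self.mean_mode not in ("global", "neighborhood"):
            raise ValueError(f"unknown mean_mode {self.mean_mode!r}")
        if self.flag_rule not in ("significant_and_high", "significant_any"):
            raise ValueError(f"unknown flag_rule {self.flag_rule!r}")
        if self.method not in ("analytic", "permutation", "both"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclasses.dataclass
class SlideSummary:
    """Slide-level outcome: zone counts and the present/absent call."""

    slide_id: str
    m_zones: int
    n_tested: int
    n_diversified: int
    fraction_diversified: float
    present: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def zone_variability(
    zone_map: ZoneMap,
    table: CellTable,
    params: DiversificationParams | None = None,
    target_class: str = "cancer",
) -> pd.DataFrame:
    """Per-zone shape variability Y_i with exclusion bookkeeping.

    Y_i is the sample standard deviation (n-1 denominator) of the shape
    factor over the zone's ``target_class`` cells.  Zones with fewer than
    ``min_cancer_cells_per_zone`` such cells are marked excluded and carry
    Y = NaN.

    Returns a frame indexed by zone_id with columns ``n_cancer``, ``Y``,
    ``excluded``, ``exclude_reason``.
    """
    params = params or DiversificationParams()
    df = table.data
    s = moran.shape_factor(df["nucleus_perimeter"], df["nucleus_area"])
    is_target = (df["cell_class"] == target_class).to_numpy()
    zone = zone_map.assignment
    rows = []
    for k in range(zone_map.m):
        mask = (zone == k) & is_target
        vals = s[mask]
        n = int(mask.sum())
        if n < params.min_cancer_cells_per_zone:
            rows.append((k, n, np.nan, True, "too_few_cells"))
        else:
            rows.append((k, n, float(np.std(vals, ddof=1)), False, ""))
    out = pd.DataFrame(
        rows, columns=["zone_id", "n_cancer", "Y", "excluded", "exclude_reason"]
    ).set_index("zone_id")
    return out


def flag_diversified(
    results: pd.DataFrame, params: DiversificationParams, y_mean: float
) -> pd.Series:
    """Apply the diversification call to a zone-results frame.

    Default rule: q < alpha AND Y above the slide's global mean Y, so only
    high-variability zones (spatial clusters or spatial outliers of high Y)
    are called.  ``significant_any`` drops the Y condition.
    """
    q = results["q"]
    sig = q.notna() & (q < params.alpha)
    if params.flag_rule == "significant_and_high":
        sig = sig & (results["Y"] > y_mean)
    return sig & ~results["excluded"].astype(bool)


def summarize_sample(results: pd.DataFrame, slide_id: str) -> SlideSummary:
    """Collapse zone results into the slide-level present/absent call."""
    tested = results[~results["excluded"].astype(bool)]
    n_div = int(results["diversified"].sum())
    frac = n_div / len(tested) if len(tested) else 0.0
    return SlideSummary(
        slide_id=slide_id,
        m_zones=int(len(results)),
        n_tested=int(len(tested)),
        n_diversified=n_div,
        fraction_diversified=frac,
        present=n_div >= 1,
    )


class DiversificationModel:
    """Diversification-zone model for one slide.

    Parameters
    ----------
    table : CellTable
        Per-cell slide table (must contain cancer cells).
    params : DiversificationParams, optional
    tessellation_config : TessellationConfig, optional
    zone_map : ZoneMap, optional
        Supply a pre-built partition to skip seeding/tessellation (useful
        for imposing one slide's tessellation onto serial-section data).
    """

    def __init__(
        self,
        table: CellTable,
        params: DiversificationParams | None = None,
        tessellation_config: TessellationConfig | None = None,
        zone_map: ZoneMap | None = None,
    ):
        self.table = table
        self.params = params or DiversificationParams()
        self.tessellation_config = tessellation_config or TessellationConfig()
        self._zone_map = zone_map
        n_target = int((table.data["cell_class"] == self.tessellation_config.target_class).sum())
        if n_target == 0:
            raise ValueError(
                f"table has no {self.tessellation_config.target_class} cells"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, slide_id: str = "slide", **kwargs
    ) -> "DiversificationModel":
        """Build a model straight from a canonical-column DataFrame."""
        return cls(CellTable(df.copy(), slide_id=slide_id), **kwargs)

    def build_zone_map(self, rng_seed: int = 0) -> ZoneMap:
        """Tissue hull -> seed count -> random cancer seeds -> Voronoi zones."""
        cfg = self.tessellation_config
        area, poly = tessellation.compute_tissue_area(
            self.table, method=cfg.tissue_method, alpha=cfg.alpha
        )
        n = cfg.n_seeds or tessellation.seed_count(area, cfg.area_unit_scale)
        n = min(n, int((self.table.data["cell_class"] == cfg.target_class).sum()))
        seeds = tessellation.select_seeds(self.table, n, rng_seed, cfg.target_class)
        return tessellation.build_zone_map(self.table, seeds, poly)

    def fit(self, rng_seed: int = 0) -> "DiversificationResults":
        """Run the full zonal test and return a results object.

        A single ``rng_seed`` governs both seed selection and (when the
        permutation route is on) the Monte-Carlo null, so identical inputs
        and seed give identical results.
        """
        params = self.params
        zone_map = self._zone_map or self.build_zone_map(rng_seed)
        weights = tessellation.neighbor_graph(zone_map)
        zv = zone_variability(zone_map, self.table, params,
                              self.tessellation_config.target_class)

        res = zv.copy()
        for col in ("I", "E_I", "Var_I", "z", "p_analytic", "p_permutation", "q"):
            res[col] = np.nan
        tested = res.index[~res["excluded"]].to_numpy()
        y_mean = float(res.loc[tested, "Y"].mean()) if len(tested) else np.nan

        if len(tested) >= 4:
            w_sub = weights.subgraph(tested)
            order = list(tested)
            y = res.loc[tested, "Y"].to_numpy()
            i_vals = moran.local_morans_i(y, w_sub, params.mean_mode, order)
            res.loc[tested, "I"] = i_vals
            use_analytic = params.method in ("analytic", "both")
            if params.mean_mode != "global":
                use_analytic = False
            if use_analytic:
                e_i, var_i, z = moran.analytic_moments(y, w_sub, order)
                res.loc[tested, "E_I"] = e_i
                res.loc[tested, "Var_I"] = var_i
                res.loc[tested, "z"] = z
                res.loc[tested, "p_analytic"] = moran.analytic_pvalues(z, params.tail)
            if params.method in ("permutation", "both") or not use_analytic:
                res.loc[tested, "p_permutation"] = moran.permutation_null(
                    y, w_sub, params.n_permutations, rng_seed, params.tail, order
                )
            p_col = "p_analytic" if use_analytic else "p_permutation"
            p = res.loc[tested, p_col].to_numpy()
            ok = np.isfinite(p)
            q = np.full(len(p), np.nan)
            if ok.any():
                q[ok] = moran.fdr_adjust(p[ok])
            res.loc[tested, "q"] = q
            # zones whose null variance degenerates cannot be tested
            degenerate = res.index[res.index.isin(tested) & res["q"].isna()]
            res.loc[degenerate, "excluded"] = True
            res.loc[degenerate, "exclude_reason"] = "degenerate_null"
        else:
            res.loc[tested, "excluded"] = True
            res.loc[tested, "exclude_reason"] = "too_few_zones"

        res["diversified"] = flag_diversified(res, params, y_mean)
        summary = summarize_sample(res, self.table.slide_id)
        return DiversificationResults(
            model=self, zone_map=zone_map, weights=weights,
            zone_results=res, slide_summary=summary,
            y_global_mean=y_mean, rng_seed=rng_seed,
        )


@dataclasses.dataclass
class DiversificationResults:
    """Fitted diversification map for one slide.

    Attributes
    ----------
    zone_results : pandas.DataFrame
        One row per zone: n_cancer, Y, I, E_I, Var_I, z, p_analytic,
        p_permutation, q, excluded, diversified.
    slide_summary : SlideSummary
        The slide-level call.
    y_global_mean : float
        Global mean of Y over tested zones (the reference of the flag rule).
    """

    model: DiversificationModel
    zone_map: ZoneMap
    weights: WeightsGraph
    zone_results: pd.DataFrame
    slide_summary: SlideSummary
    y_global_mean: float
    rng_seed: int

    @property
    def diversified_zones(self) -> np.ndarray:
        return self.zone_results.index[self.zone_results["diversified"]].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self.zone_results.copy()

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        s = self.slide_summary
        r = self.zone_results
        tested = r[~r["excluded"].astype(bool)]
        lines = [
            "Morphological diversification zones",
            "=" * 47,
            f"Slide:                    {s.slide_id}",
            f"Zones (tessellated):      {s.m_zones}",
            f"Zones tested:             {s.n_tested}",
            f"Diversified zones:        {s.n_diversified}",
            f"Fraction diversified:     {s.fraction_diversified:.4f}",
            f"Diversification present:  {s.present}",
            "-" * 47,
            f"Global mean Y:            {self.y_global_mean:.4f}",
            f"Y range (tested):         "
            f"[{tested['Y'].min():.4f}, {tested['Y'].max():.4f}]"
            if len(tested) else "Y range (tested):         n/a",
            f"alpha (FDR):              {self.model.params.alpha}",
            f"tail / flag rule:         {self.model.params.tail} / "
            f"{self.model.params.flag_rule}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def plot_zones(self, ax=None, cmap: str = "viridis"):
        """Choropleth of zonal Y with diversified zones outlined."""
        import matplotlib.pyplot as plt
        from matplotlib.collections import PatchCollection
        from matplotlib.patches import Polygon as MplPolygon

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        r = self.zone_results
        patches, values = [], []
        for k, poly in enumerate(self.zone_map.regions):
            patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
            values.append(r.at[k, "Y"])
        coll = PatchCollection(patches, cmap=cmap, edgecolor="white",
                               linewidth=0.3)
        coll.set_array(np.asarray(values, dtype=float))
        ax.add_collection(coll)
        for k in self.diversified_zones:
            xs, ys = self.zone_map.regions[k].exterior.xy
            ax.plot(xs, ys, color="limegreen", linewidth=1.6)
        ax.autoscale_view()
        ax.set_aspect("equal")
        ax.invert_yaxis()  # image convention: y grows downward
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        plt.colorbar(coll, ax=ax, label="zonal shape variability Y")
        return ax


def run_pipeline(
    table: CellTable,
    params: DiversificationParams | None = None,
    tessellation_config: TessellationConfig | None = None,
    rng_seed: int = 0,
) -> tuple[ZoneMap, pd.DataFrame, SlideSummary]:
    """One-call pipeline: tessellate, test, flag and summarize a slide."""
    res = DiversificationModel(table, params, tessellation_config).fit(rng_seed)
    return res.zone_map, res.zone_results, res.slide_summary
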