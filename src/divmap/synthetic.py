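"""Synthetic whole-slide cell maps with planted diversification zones.

The generator emulates the per-cell tables that whole-slide H&E image
analysis would produce for a tumor section: spatially clustered cancer,
lymphocyte and stromal cells; lognormal nuclear areas; and a per-cell
nuclear shape factor s >= 1 synthesized as s = 1 + exp(N(mu, sigma)).
Diversification zones are planted as circles inside which sigma is
multiplied by a variance factor — the spread of the shape factor is
inflated, not its mean, matching what the zonal statistic (a standard
deviation) is designed to detect.  The perimeter of each nucleus is
back-computed from its sampled shape factor and area,
p = s * 2*sqrt(pi*a), so ground-truth shape factors are exact by
construction.  Optionally, lymphocytes that fall inside a planted circle
are displaced outside it with a configurable probability, emulating local
immune depletion while keeping class counts exact.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CellTable
from .tessellation import ZoneMap


@dataclasses.dataclass
class PlantedZone:
    """A circular region of elevated shape-factor variance."""

    x: float
    y: float
    radius: float
    variance_multiplier: float = 3.0
    lymphocyte_depletion: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.variance_multiplier < 1:
            raise ValueError("variance_multiplier must be >= 1")
        if not 0 <= self.lymphocyte_depletion <= 1:
            raise ValueError("lymphocyte_depletion must be in [0, 1]")

    def contains(self, x, y) -> np.ndarray:
        return (np.asarray(x) - self.x) ** 2 + (np.asarray(y) - self.y) ** 2 \
            <= self.radius ** 2


@dataclasses.dataclass
class SyntheticSlideConfig:
    """Study conditions for one synthetic slide.

    Defaults are the desk-scale conditions: a 5x5 mm section carrying
    20,000 cancer cells with lymphocyte/stromal counts in the cohort-average
    proportions (~71% / 13.5% / 15.3%), cells clustered by a Thomas process,
    and three planted circles of radius 250 µm with 3x shape-variance
    inflation.  Baseline morphometry: nuclear area lognormal around 30 µm²,
    shape factor 1 + exp(N(-1.5, 0.5)) (median ~1.22).
    """

    width: float = 5000.0
    height: float = 5000.0
    n_cancer: int = 20_000
    n_lymphocyte: int = 3_800
    n_stromal: int = 4_300
    spatial_clustering: str = "thomas"  # or "uniform"
    parent_intensity: float = 2e-6     # Thomas parents per µm²
    cluster_sd: float = 200.0          # Thomas offspring spread, µm
    base_logshape_mean: float = -1.5
    base_logshape_sd: float = 0.5
    nucleus_area_logmean: float = float(np.log(30.0))
    nucleus_area_logsd: float = 0.35
    planted_zones: Sequence[PlantedZone] = dataclasses.field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer", "n_lymphocyte", "n_stromal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("slide dimensions must be positive")
        zones = []
        for z in self.planted_zones:
            if isinstance(z, dict):
                z = PlantedZone(**z)
            elif isinstance(z, (tuple, list)):
                z = PlantedZone(*z)
            if not (0 <= z.x <= self.width and 0 <= z.y <= self.height):
                raise ValueError("planted zone center outside slide bounds")
            if (z.x - z.radius < 0 or z.x + z.radius > self.width
                    or z.y - z.radius < 0 or z.y + z.radius > self.height):
                raise ValueError("planted zone extends outside slide bounds")
            zones.append(z)
        self.planted_zones = zones

    @classmethod
    def default_desk_scale(cls, planted: bool = True, rng_seed: int = 0,
                           variance_multiplier: float = 3.0,
                           lymphocyte_depletion: float = 0.0) -> "SyntheticSlideConfig":
        """The default study conditions, with or without planted circles."""
        zones = []
        if planted:
            zones = [
                PlantedZone(1250.0, 1250.0, 250.0, variance_multiplier,
                            lymphocyte_depletion),
                PlantedZone(3750.0, 1600.0, 250.0, variance_multiplier,
                            lymphocyte_depletion),
                PlantedZone(2500.0, 3750.0, 250.0, variance_multiplier,
                            lymphocyte_depletion),
            ]
        return cls(planted_zones=zones, rng_seed=rng_seed)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSlideConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


@dataclasses.dataclass
class GroundTruth:
    """What was planted: circle geometries plus per-cell membership."""

    slide_id: str
    planted_zones: list
    per_cell_in_planted: np.ndarray  # bool, aligned with table rows

    def circles_geojson(self) -> dict:
        feats = []
        for z in self.planted_zones:
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [z.x, z.y]},
                "properties": {
                    "radius": z.radius,
                    "variance_multiplier": z.variance_multiplier,
                    "lymphocyte_depletion": z.lymphocyte_depletion,
                },
            })
        return {"type": "FeatureCollection", "features": feats}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "slide_id": self.slide_id,
                "circles": self.circles_geojson(),
                "per_cell_in_planted": self.per_cell_in_planted.astype(int).tolist(),
            }, fh)


def _positions(n: int, cfg: SyntheticSlideConfig, rng: np.random.Generator) -> np.ndarray:
    """Cell positions: uniform, or a Thomas cluster process conditioned on n."""
    if n == 0:
        return np.empty((0, 2))
    if cfg.spatial_clustering == "uniform":
        return rng.uniform([0, 0], [cfg.width, cfg.height], size=(n, 2))
    if cfg.spatial_clustering != "thomas":
        raise ValueError(f"unknown spatial_clustering {cfg.spatial_clustering!r}")
    area = cfg.width * cfg.height
    n_parents = max(1, rng.poisson(cfg.parent_intensity * area))
    parents = rng.uniform([0, 0], [cfg.width, cfg.height], size=(n_parents, 2))
    which = rng.integers(n_parents, size=n)
    pos = parents[which] + rng.normal(0.0, cfg.cluster_sd, size=(n, 2))
    # resample offspring that land off the slide (keeps n exact)
    bad = ~_inside(pos, cfg)
    while bad.any():
        k = int(bad.sum())
        which = rng.integers(n_parents, size=k)
        pos[bad] = parents[which] + rng.normal(0.0, cfg.cluster_sd, size=(k, 2))
        bad = ~_inside(pos, cfg)
    return pos


def _inside(pos: np.ndarray, cfg: SyntheticSlideConfig) -> np.ndarray:
    return ((pos[:, 0] >= 0) & (pos[:, 0] <= cfg.width)
            & (pos[:, 1] >= 0) & (pos[:, 1] <= cfg.height))


def _in_any_zone(pos: np.ndarray, zones) -> np.ndarray:
    inside = np.zeros(len(pos), dtype=bool)
    for z in zones:
        inside |= z.contains(pos[:, 0], pos[:, 1])
    return inside


def generate_slide(
    config: SyntheticSlideConfig, slide_id: str = "synthetic"
) -> tuple[CellTable, GroundTruth]:
    """Generate one synthetic slide and its ground truth.

    Fully reproducible from ``config.rng_seed``; class counts match the
    config exactly.  Shape factors of cells inside a planted circle are
    drawn with the log-scale sigma multiplied by that circle's
    ``variance_multiplier``; lymphocytes landing inside a circle are
    displaced outside it with probability ``lymphocyte_depletion``.
    """
    # one independent child stream per stage and class, so changing one
    # knob (e.g. lymphocyte depletion) leaves every other draw untouched
    root = np.random.default_rng(config.rng_seed)
    streams = {name: rng for name, rng in zip(
        ("pos_cancer", "pos_lymphocyte", "pos_stromal", "depletion",
         "shape_cancer", "shape_lymphocyte", "shape_stromal"),
        root.spawn(7))}
    parts = []
    for cls_name, n in (("cancer", config.n_cancer),
                        ("lymphocyte", config.n_lymphocyte),
                        ("stromal", config.n_stromal)):
        pos = _positions(n, config, streams[f"pos_{cls_name}"])
        if cls_name == "lymphocyte" and config.planted_zones:
            pos = _deplete_lymphocytes(pos, config, streams["depletion"])
        parts.append((cls_name, pos))

    frames = []
    offset = 0
    for cls_name, pos in parts:
        rng = streams[f"shape_{cls_name}"]
        n = len(pos)
        sigma = np.full(n, config.base_logshape_sd)
        in_planted = np.zeros(n, dtype=bool)
        for z in config.planted_zones:
            hit = z.contains(pos[:, 0], pos[:, 1])
            sigma = np.where(hit, config.base_logshape_sd * z.variance_multiplier,
                             sigma)
            in_planted |= hit
        s = 1.0 + np.exp(config.base_logshape_mean
                         + sigma * rng.standard_normal(n))
        area = rng.lognormal(config.nucleus_area_logmean,
                             config.nucleus_area_logsd, size=n)
        perimeter = s * 2.0 * np.sqrt(np.pi * area)
        frames.append(pd.DataFrame({
            "cell_id": np.arange(offset, offset + n),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "cell_class": cls_name,
            "nucleus_area": area,
            "nucleus_perimeter": perimeter,
            "_in_planted": in_planted,
        }))
        offset += n
    df = pd.concat(frames, ignore_index=True)
    in_planted = df.pop("_in_planted").to_numpy()
    table = CellTable(df, slide_id=slide_id)
    truth = GroundTruth(slide_id=slide_id,
                        planted_zones=list(config.planted_zones),
                        per_cell_in_planted=in_planted)
    return table, truth


def _deplete_lymphocytes(pos: np.ndarray, cfg: SyntheticSlideConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Displace in-circle lymphocytes outside all circles with the planted
    depletion probability (counts stay exact: depletion is displacement)."""
    pos = pos.copy()
    for z in cfg.planted_zones:
        if z.lymphocyte_depletion == 0:
            continue
        hit = np.flatnonzero(z.contains(pos[:, 0], pos[:, 1]))
        move = hit[rng.random(len(hit)) < z.lymphocyte_depletion]
        k = len(move)
        while k:
            cand = rng.uniform([0, 0], [cfg.width, cfg.height], size=(k, 2))
            ok = ~_in_any_zone(cand, cfg.planted_zones)
            pos[move[ok]] = cand[ok]
            move = move[~ok]
            k = len(move)
    return pos


def match_zones_to_truth(
    zone_map: ZoneMap,
    table: CellTable,
    truth: GroundTruth,
    overlap_threshold: float = 0.5,
    target_class: str = "cancer",
) -> pd.Series:
    """Label each tessellated zone true/false against the planted circles.

    A zone is labeled true when at least ``overlap_threshold`` of its
    ``target_class`` cells lie inside some planted circle.
    """
    if zone_map.slide_id != truth.slide_id:
        raise ValueError(
            f"zone map is from slide {zone_map.slide_id!r} but ground truth "
            f"from {truth.slide_id!r}"
        )
    df = table.data
    is_target = (df["cell_class"] == target_class).to_numpy()
    xy = table.coords
    in_circle = np.zeros(len(df), dtype=bool)
    for z in truth.planted_zones:
        in_circle |= z.contains(xy[:, 0], xy[:, 1])
    labels = {}
    for k in range(zone_map.m):
        mask = (zone_map.assignment == k) & is_target
        n = int(mask.sum())
        labels[k] = bool(n > 0 and in_circle[mask].sum() / n >= overlap_threshold)
    return pd.Series(labels, name="planted")


def recovery_metrics(predicted, truth) -> dict:
    """Confusion-matrix ratios of a zone-level recovery experiment.

    Returns sensitivity, specificity, precision and F1; ratios with an
    empty denominator are reported as None rather than 0.
    """
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    if pred.shape != tru.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int((pred & tru).sum())
    fn = int((~pred & tru).sum())
    fp = int((pred & ~tru).sum())
    tn = int((~pred & ~tru).sum())

    def _ratio(num, den):
        return num / den if den else None

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "F1": f1, "tp": tp, "fn": fn, "fp": fp, "tn": tn}
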