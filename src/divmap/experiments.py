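"""Desk-scale simulation experiments: planted-zone recovery, null
calibration, and lymphocyte-depletion trend power.

These are the standing evaluation experiments of the package: each one
generates synthetic slides under the default desk-scale conditions, runs
the detection pipeline, and measures how well known planted structure is
recovered.  Slide seeds are spawned deterministically from a single base
seed so every experiment is reproducible end to end.
"""

from __future__ import annotations

import numpy as np

from . import context as context_mod
from .model import DiversificationModel, DiversificationParams, TessellationConfig
from .synthetic import (
    SyntheticSlideConfig,
    generate_slide,
    match_zones_to_truth,
    recovery_metrics,
)


def _spawn_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def recovery_experiment(
    base_seed: int = 0,
    n_slides: int = 30,
    variance_multiplier: float = 3.0,
    overlap_threshold: float = 0.5,
    params: DiversificationParams | None = None,
    tessellation_config: TessellationConfig | None = None,
) -> dict:
    """Planted-zone recovery pooled over desk-scale slides.

    Generates ``n_slides`` default desk-scale slides with planted circles
    at the given variance multiplier, fits the model on each, labels zones
    against ground truth, and pools the confusion matrix across slides
    (pooling stabilizes the ratio estimates: a single slide has only
    ~10 truth zones).
    """
    seeds = _spawn_seeds(base_seed, n_slides)
    tp = fn = fp = tn = 0
    n_present = 0
    for seed in seeds:
        cfg = SyntheticSlideConfig.default_desk_scale(
            rng_seed=seed, variance_multiplier=variance_multiplier)
        table, truth = generate_slide(cfg)
        res = DiversificationModel(table, params, tessellation_config).fit(seed)
        labels = match_zones_to_truth(res.zone_map, table, truth,
                                      overlap_threshold)
        m = recovery_metrics(res.zone_results["diversified"].to_numpy(),
                             labels.to_numpy())
        tp += m["tp"]; fn += m["fn"]; fp += m["fp"]; tn += m["tn"]
        n_present += res.slide_summary.present
    out = recovery_metrics(
        np.concatenate([np.ones(tp + fp, bool), np.zeros(fn + tn, bool)]),
        np.concatenate([np.ones(tp, bool), np.zeros(fp, bool),
                        np.ones(fn, bool), np.zeros(tn, bool)]),
    )
    out["n_slides"] = len(seeds)
    out["present_fraction"] = n_present / len(seeds)
    return out


def null_calibration_experiment(
    base_seed: int = 0,
    n_slides: int = 50,
    params: DiversificationParams | None = None,
    tessellation_config: TessellationConfig | None = None,
) -> dict:
    """False-discovery behaviour on slides with nothing planted.

    Runs the pipeline on ``n_slides`` null desk-scale slides (no planted
    circles) and reports the mean flagged-zone fraction and the fraction
    of slides called "present".  Under FDR control at alpha the mean
    flagged fraction should not exceed alpha.
    """
    seeds = _spawn_seeds(base_seed, n_slides)
    fractions = []
    present = 0
    for seed in seeds:
        cfg = SyntheticSlideConfig.default_desk_scale(planted=False,
                                                      rng_seed=seed)
        table, _ = generate_slide(cfg)
        res = DiversificationModel(table, params, tessellation_config).fit(seed)
        fractions.append(res.slide_summary.fraction_diversified)
        present += res.slide_summary.present
    return {
        "n_slides": len(seeds),
        "mean_flagged_fraction": float(np.mean(fractions)),
        "max_flagged_fraction": float(np.max(fractions)),
        "present_fraction": present / len(seeds),
    }


def depletion_trend_experiment(
    base_seed: int = 0,
    depletions: tuple = (0.0, 0.5, 1.0),
    n_slides: int = 8,
    alpha: float = 0.05,
) -> dict:
    """Power of the zonal lymphocyte trend test vs planted depletion.

    For each depletion level, generates planted slides (variance 3x,
    lymphocytes displaced out of the circles with the given probability),
    recovers diversification flags, orders zones diversified < adjacent <
    rest, and runs the Jonckheere trend test with the *increasing*
    alternative (lymphocyte abundance rising away from diversified zones).
    Reports the rejection rate at ``alpha`` per depletion level; power
    should increase with the planted depletion.  The same slide seeds are
    reused at every level (common random numbers): cancer cells, zones and
    flags are then identical across levels and only the lymphocyte
    placement differs, so the power curve is paired and monotone in
    expectation.
    """
    seeds = _spawn_seeds(base_seed, n_slides)
    power = {}
    for dep in depletions:
        rejections = 0
        tested = 0
        for seed in seeds:
            cfg = SyntheticSlideConfig.default_desk_scale(
                rng_seed=seed, lymphocyte_depletion=dep)
            table, _ = generate_slide(cfg)
            res = DiversificationModel(table).fit(seed)
            if not res.slide_summary.present:
                continue
            comp = context_mod.zone_composition(res.zone_map, table)
            groups = context_mod.zonal_groups(
                res.zone_results["diversified"], res.weights)
            ok = comp["n_total"] > 0
            _, p = context_mod.jonckheere_test(
                comp.loc[ok, "lymphocyte_fraction"], groups[ok],
                alternative="increasing")
            tested += 1
            rejections += p < alpha
        power[dep] = rejections / tested if tested else float("nan")
    return {"power_by_depletion": power, "n_slides_per_level": n_slides}
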