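"""Validation studies run on the synthetic default conditions.

Each function generates its own data from a seed, runs the relevant part
of the pipeline, and returns summary numbers. They back both the test
suite and the reproduction script, so every reported quantity is
recomputed from scratch at call time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import atlas, metrics, pipeline, synthetic
from .grid import AnalysisGrid


def recovery_study(n_mice: int = 50, seed: int = 0,
                   tolerance_um: float = 50.0) -> dict:
    """Segmentation + registration ground-truth recovery.

    Default conditions: acquisition noise on and a 100-um human alignment
    error on the skull marks. Reports the fraction of rendered frequency
    domains detected, the fraction recovered within ``tolerance_um``, the
    centroid-error distribution, and the rotation-recovery error.
    """
    run = pipeline.run_synthetic_population(n_mice, seed=seed)
    errs = run.centroid_errors_um
    rot = np.abs(run.rotation_errors_rad)
    return {
        "n_mice": n_mice,
        "n_domains": int(sum(e.n_rendered for e in run.evaluations)),
        "detection_rate": float(run.detection_rate),
        "fraction_within_tolerance": float(run.detection_rate_within(tolerance_um)),
        "median_centroid_error_um": float(np.median(errs)),
        "max_rotation_error_rad": float(rot.max()),
        "mean_rotation_error_rad": float(rot.mean()),
        "run": run,
    }


def _translation_only_params(sigma_um: float) -> synthetic.PopulationParams:
    return synthetic.PopulationParams(
        translation_sd_um=(sigma_um, sigma_um),
        rotation_sd_rad=0.0, bldist_sd_mm=0.0, gap_sd_um=0.0,
        amplitude_jitter=(1.0, 1.0), scale_jitter_frac=0.0,
        strain_probs={"B6": 1.0}, sex_probs={"M": 1.0},
    )


def pairwise_distance_closed_form_study(
    n_mice: int = 50, sigma_um: float = 400.0,
    replicates: int = 40, seed: int = 0,
) -> dict:
    """Expectation of the n-mouse pairwise centroid-distance statistic.

    Populations carry a pure whole-cortex translation of per-axis SD
    ``sigma_um``; the per-axis mean |distance| between corresponding
    domain centroids over all mouse pairs then has expectation
    ``2 sigma / sqrt(pi)`` (|N(0, 2 sigma^2)|). A single n=50 draw of the
    statistic has ~11% relative SE, so the statistic is averaged over
    independent replicate populations to estimate its expectation.
    """
    params = _translation_only_params(sigma_um)
    grid = AnalysisGrid()
    root = np.random.SeedSequence(seed)
    ap_means, dv_means = [], []
    for child in root.spawn(replicates):
        layouts = synthetic.sample_population_layouts(
            params, n_mice, np.random.default_rng(child)
        )
        mice = [
            metrics.MouseRecord(f"m{i}", {}, dict(l.centers_mm))
            for i, l in enumerate(layouts)
        ]
        out = metrics.centroid_pairwise_distances(
            metrics.PopulationMaps(grid=grid, mice=mice)
        )
        ap_means.append(out["mean_ap_mm"] * 1000.0)
        dv_means.append(out["mean_dv_mm"] * 1000.0)
    expected = 2 * sigma_um / np.sqrt(np.pi)
    return {
        "n_mice": n_mice,
        "replicates": replicates,
        "mean_ap_um": float(np.mean(ap_means)),
        "mean_dv_um": float(np.mean(dv_means)),
        "expected_um": float(expected),
    }


def human_error_closed_form_study(
    n_mice: int = 1500, sd_um: float = 100.0, seed: int = 0
) -> dict:
    """Inter-experimenter marking error against its closed form.

    Each animal is marked twice with independent alignment errors of SD
    ``sd_um`` per axis; the per-axis error metric then has expectation
    ``2 sd / sqrt(pi)``.
    """
    layouts = synthetic.sample_population_layouts(
        _translation_only_params(0.0), 1, np.random.default_rng(seed + 1)
    )
    layout = layouts[0]
    rng = np.random.default_rng(seed)
    ap, dv = [], []
    for _ in range(n_mice):
        a = synthetic.place_reference_marks(layout, sd_um, rng)
        b = synthetic.place_reference_marks(layout, sd_um, rng)
        out = metrics.human_error_metric(
            layout.transform.px_to_mm(a.pixels),
            layout.transform.px_to_mm(b.pixels),
        )
        ap.append(out["ap_mm"] * 1000.0)
        dv.append(out["dv_mm"] * 1000.0)
    expected = 2 * sd_um / np.sqrt(np.pi)
    return {
        "n_mice": n_mice,
        "mean_ap_um": float(np.mean(ap)),
        "mean_dv_um": float(np.mean(dv)),
        "expected_um": float(expected),
    }


def population_study(n_mice: int = 41, seed: int = 0) -> dict:
    """The full population comparison against the (synthetic) atlas map.

    Mirrors the study design: image and parcellate ``n_mice`` animals,
    register them into BL-normalized coordinates, and quantify atlas
    overlap, classification and targeting accuracy, cross-animal mask
    overlap, centroid variability, and the variance decomposition of the
    auditory-cortex centroid over strain, sex and age.
    """
    run = pipeline.run_synthetic_population(n_mice, seed=seed)
    pop = run.population
    table = atlas.patch_discontinuity(atlas.synthetic_atlas_table())
    rasters = atlas.atlas_rasters(atlas.build_surface_map(table), pop.grid)

    rows = []
    for mouse in pop.mice:
        row = {"mouse_id": mouse.mouse_id, **mouse.meta}
        row.update(metrics.classification_accuracy(mouse, rasters))
        row.update(metrics.targeting_accuracy(mouse, rasters))
        rows.append(row)
    acc = pd.DataFrame(rows)

    overlaps = {
        area: metrics.pairwise_population_overlap(pop, area)
        for area in metrics.TONOTOPIC_AREAS
    }
    dists = metrics.centroid_pairwise_distances(pop)

    centroids = []
    for mouse in pop.mice:
        try:
            c = metrics.auditory_cortex_centroid(mouse)
        except ValueError:
            continue
        centroids.append({"ap": c[0], "dv": c[1], **mouse.meta})
    cdf = pd.DataFrame(centroids).rename(columns={"age_wk": "age"})
    shares = {
        axis: metrics.variance_decomposition(cdf, axis)
        for axis in ("ap", "dv")
    }

    fractions = []
    for mouse in pop.mice:
        df = metrics.map_functional_onto_atlas(mouse, rasters)
        df.insert(0, "mouse_id", mouse.mouse_id)
        fractions.append(df)

    return {
        "n_mice": n_mice,
        "run": run,
        "population": pop,
        "atlas_rasters": rasters,
        "accuracy": acc,
        "pairwise_overlap": overlaps,
        "centroid_distances": dists,
        "variance_shares": shares,
        "functional_onto_atlas": pd.concat(fractions),
    }
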