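"""File formats: TIFF trial stacks, YAML sidecars, CSV tables, GeoJSON masks.

A synthetic session on disk is one multi-page TIFF per tone frequency
(frames in acquisition order), a YAML sidecar holding the acquisition
configuration and ground truth, and a CSV of the skull reference marks.
Segmentation results export as 0/255 PNG masks, GeoJSON polygons and a
per-domain CSV table; fitted transforms as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import synthetic
from .coords import StereotaxicTransform
from .imaging import TrialStack

MARKS_COLUMNS = ("mouse_id", "mark_index", "px_x", "px_y",
                 "nominal_P_mm", "nominal_V_mm")


def _layout_to_dict(layout: synthetic.GroundTruthLayout) -> dict:
    return {
        "centers_mm": {f"{a}:{f:g}": [float(c[0]), float(c[1])]
                       for (a, f), c in layout.centers_mm.items()},
        "amplitudes": {f"{a}:{f:g}": float(v)
                       for (a, f), v in layout.amplitudes.items()},
        "rotation_rad": float(layout.rotation_rad),
        "scale_ap_um": float(layout.scale_ap_um),
        "scale_dv_um": float(layout.scale_dv_um),
        "bldist_mm": float(layout.bldist_mm),
        "bregma_px": [float(v) for v in layout.bregma_px],
        "translation_mm": [float(v) for v in layout.translation_mm],
        "gap_mm": float(layout.gap_mm),
        "domain_sigma_um": float(layout.domain_sigma_um),
        "strain": layout.strain,
        "sex": layout.sex,
        "age_wk": float(layout.age_wk),
        "image_size_px": int(layout.image_size_px),
    }


def _layout_from_dict(d: dict) -> synthetic.GroundTruthLayout:
    def parse_key(k):
        a, f = k.split(":")
        return a, float(f)

    return synthetic.GroundTruthLayout(
        centers_mm={parse_key(k): np.asarray(v, float)
                    for k, v in d["centers_mm"].items()},
        amplitudes={parse_key(k): float(v) for k, v in d["amplitudes"].items()},
        rotation_rad=d["rotation_rad"],
        scale_ap_um=d["scale_ap_um"],
        scale_dv_um=d["scale_dv_um"],
        bldist_mm=d["bldist_mm"],
        bregma_px=np.asarray(d["bregma_px"], float),
        translation_mm=np.asarray(d["translation_mm"], float),
        gap_mm=d["gap_mm"],
        domain_sigma_um=d["domain_sigma_um"],
        strain=d["strain"],
        sex=d["sex"],
        age_wk=d["age_wk"],
        image_size_px=d["image_size_px"],
    )


def write_session(session: synthetic.SyntheticSession, out_dir) -> Path:
    """Write one synthetic session: TIFFs + YAML sidecar + marks CSV."""
    out = Path(out_dir) / session.mouse_id
    out.mkdir(parents=True, exist_ok=True)
    for freq, stack in session.stacks.items():
        flat = stack.frames.reshape(-1, *stack.frames.shape[2:])
        tifffile.imwrite(out / f"stack_{freq:g}khz.tif", flat)
    sidecar = {
        "mouse_id": session.mouse_id,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(session.config).items()},
        "ground_truth": _layout_to_dict(session.layout),
    }
    (out / "session.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    rows = [
        {
            "mouse_id": session.mouse_id,
            "mark_index": i + 1,
            "px_x": float(session.marks.pixels[i, 0]),
            "px_y": float(session.marks.pixels[i, 1]),
            "nominal_P_mm": float(session.marks.nominal_mm[i, 0]),
            "nominal_V_mm": float(session.marks.nominal_mm[i, 1]),
        }
        for i in range(3)
    ]
    pd.DataFrame(rows, columns=MARKS_COLUMNS).to_csv(out / "marks.csv", index=False)
    return out


def read_session(session_dir) -> synthetic.SyntheticSession:
    """Read a session written by :func:`write_session`."""
    d = Path(session_dir)
    sidecar = yaml.safe_load((d / "session.yaml").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["response_window_s"] = tuple(cfg_dict["response_window_s"])
    config = synthetic.AcquisitionConfig(**cfg_dict)
    layout = _layout_from_dict(sidecar["ground_truth"])
    stacks = {}
    for path in sorted(d.glob("stack_*khz.tif")):
        freq = float(path.stem.replace("stack_", "").replace("khz", ""))
        flat = tifffile.imread(path)
        frames = flat.reshape(config.n_trials, config.n_frames, *flat.shape[1:])
        stacks[freq] = TrialStack(
            frames=frames,
            frame_rate_hz=config.frame_rate_hz,
            stim_onset_s=config.baseline_s,
            frequency_khz=freq,
        )
    marks_df = pd.read_csv(d / "marks.csv").sort_values("mark_index")
    marks = synthetic.MarkPlacement(
        pixels=marks_df[["px_x", "px_y"]].to_numpy(float),
        nominal_mm=marks_df[["nominal_P_mm", "nominal_V_mm"]].to_numpy(float),
        bldist_mm=layout.bldist_mm,
        in_image=np.ones(3, dtype=bool),
    )
    return synthetic.SyntheticSession(
        layout=layout, config=config, stacks=stacks, marks=marks,
        mouse_id=sidecar["mouse_id"],
    )


def read_marks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MARKS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marks CSV is missing columns {missing}")
    return df


# ----------------------------------------------------------------------
# segmentation / registration exports
# ----------------------------------------------------------------------

def write_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def polygon_to_geojson_feature(geometry, properties: dict) -> dict:
    from shapely.geometry import mapping

    return {"type": "Feature", "geometry": mapping(geometry),
            "properties": properties}


def write_geojson(features: list, path) -> None:
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1
    ))


def read_seed_rois_geojson(path, shape: tuple[int, int]) -> dict:
    """Seed ROI polygons (pixel coordinates) -> boolean masks.

    Features must carry ``area`` and ``frequency_khz`` properties.
    """
    from skimage.draw import polygon as draw_polygon

    data = json.loads(Path(path).read_text())
    rois = {}
    for feat in data["features"]:
        props = feat["properties"]
        coords = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        rr, cc = draw_polygon(coords[:, 1], coords[:, 0], shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        rois[(props["area"], float(props["frequency_khz"]))] = mask
    return rois


def write_segmentation(seg, out_dir, transform=None) -> Path:
    """Masks as PNG + GeoJSON, per-domain table as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (area, freq), dom in sorted(seg.domains.items()):
        rows.append({
            "area": area, "freq_khz": freq,
            "centroid_px_x": float(dom.centroid_px[0]),
            "centroid_px_y": float(dom.centroid_px[1]),
            "peak_amp": float(dom.peak_amplitude),
            "n_pixels": int(dom.mask.sum()),
        })
    pd.DataFrame(rows).to_csv(out / "domains.csv", index=False)
    features = []
    for name, am in seg.all_area_masks().items():
        write_mask_png(am.mask, out / f"mask_{name}.png")
        if transform is not None:
            from .pipeline import mask_to_polygon

            poly = mask_to_polygon(am.mask, transform)
            features.append(polygon_to_geojson_feature(
                poly, {"area": name, "system": transform.system}
            ))
    if features:
        write_geojson(features, out / "areas.geojson")
    return out


def write_transform_yaml(transform: StereotaxicTransform, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "theta_rad": float(transform.theta_rad),
        "scale_ap_um": float(transform.scale_ap_um),
        "scale_dv_um": float(transform.scale_dv_um),
        "bregma_px": [float(v) for v in transform.bregma_px],
        "bldist_mm": float(transform.bldist_mm),
        "system": transform.system,
    }))


def read_transform_yaml(path) -> StereotaxicTransform:
    d = yaml.safe_load(Path(path).read_text())
    return StereotaxicTransform(
        theta_rad=d["theta_rad"],
        scale_ap_um=d["scale_ap_um"],
        scale_dv_um=d["scale_dv_um"],
        bregma_px=np.asarray(d["bregma_px"], float),
        bldist_mm=d["bldist_mm"],
        system=d.get("system", "bregma_absolute"),
    )
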