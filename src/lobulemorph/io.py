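"""File I/O for images, masks, geometry and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segmentation import ClassMasks, SegmentedObject
from .synthetic import SyntheticLobule, VesselSpec
from .topology import BranchPoint


def save_image(path, image: np.ndarray) -> None:
    """Write a grayscale image; .tif keeps float32, .png is scaled uint8."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        iio.imwrite(path, np.clip(image, 0, 255).astype(np.uint8))


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(float)
    img = iio.imread(path)
    if img.ndim == 3:               # RGB -> luminance
        img = img[..., :3].mean(axis=-1)
    return img.astype(float)


def save_masks(path, masks: ClassMasks) -> None:
    """Labelled 16-bit TIFF: 0 bg, 1 vessel, 2 hepatocyte, 3 nucleus."""
    tifffile.imwrite(Path(path), masks.as_labels())


def load_masks(path, scale: float) -> ClassMasks:
    lab = tifffile.imread(Path(path))
    return ClassMasks(vessel=lab == 1, hepatocyte=lab == 2,
                      nucleus=lab == 3, scale=scale)


def objects_to_csv(path, objects: list[SegmentedObject]) -> None:
    pd.DataFrame([{"id": o.id, "class": o.class_label, "area_um2": o.area,
                   "centroid_x_um": o.centroid[0], "centroid_y_um": o.centroid[1]}
                  for o in objects]).to_csv(path, index=False)


def objects_from_csv(path) -> list[SegmentedObject]:
    df = pd.read_csv(path)
    return [SegmentedObject(id=int(r.id), class_label=r["class"],
                            area=float(r.area_um2),
                            centroid=(float(r.centroid_x_um),
                                      float(r.centroid_y_um)))
            for _, r in df.iterrows()]


def branch_points_to_csv(path, branch_points: list[BranchPoint],
                         radii=None) -> None:
    rows = []
    for i, bp in enumerate(branch_points):
        row = {"x_um": bp.x, "y_um": bp.y, "type": bp.type, "degree": bp.degree}
        if radii is not None:
            row["R"] = radii[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def branch_points_from_csv(path) -> list[BranchPoint]:
    df = pd.read_csv(path)
    return [BranchPoint(x=float(r.x_um), y=float(r.y_um), type=r.type,
                        degree=int(r.degree)) for _, r in df.iterrows()]


def geometry_to_json(path, lobule: SyntheticLobule) -> None:
    """Vessel tree + nuclei + parameters as JSON (µm, CV-centred)."""
    payload = {
        "seed": lobule.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(lobule.params).items()},
        "vessels": [{
            "centerline": v.centerline.tolist(),
            "radius_profile": v.radius_profile.tolist(),
            "internal_pressure": (None if v.internal_pressure is None
                                  else v.internal_pressure.tolist()),
            "parent": v.parent,
        } for v in lobule.vessels],
        "nuclei": lobule.nuclei.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def geometry_from_json(path) -> SyntheticLobule:
    from .synthetic import LobuleParams

    payload = json.loads(Path(path).read_text())
    raw = payload["params"]
    raw["child_lateral_offset"] = tuple(raw["child_lateral_offset"])
    params = LobuleParams(**raw)
    vessels = [VesselSpec(centerline=np.array(v["centerline"]),
                          radius_profile=np.array(v["radius_profile"]),
                          internal_pressure=(None if v["internal_pressure"] is None
                                             else np.array(v["internal_pressure"])),
                          parent=v["parent"])
               for v in payload["vessels"]]
    return SyntheticLobule(params=params, vessels=vessels,
                           nuclei=np.array(payload["nuclei"]),
                           seed=payload["seed"])
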