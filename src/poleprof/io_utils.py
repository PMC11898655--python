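"""Reading and writing scenes, stacks, profiles and tabular outputs.

Scenes are stored as one multi-page TIFF per channel set (pages = channels,
channel names in a JSON sidecar) plus a 16-bit labeled TIFF; spectral stacks
as multi-page TIFF with the wavelength grid in a JSON sidecar.  All tabular
outputs are CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .profiles import IntensityProfile, MeanProfile
from .synthgen import GroundTruth, ImageScene, SpectralScene

__all__ = [
    "write_scene", "read_scene", "write_spectral_scene", "read_spectral_scene",
    "write_ground_truth", "write_profiles_csv", "read_profiles_csv",
    "write_mean_profile_csv", "sha256_of", "write_json",
]


def write_scene(scene: ImageScene, directory: Path, stem: str) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = sorted(scene.channels)
    stack = np.stack([scene.channels[n] for n in names]).astype(np.float32)
    img_path = directory / f"{stem}.tif"
    lab_path = directory / f"{stem}_labels.tif"
    meta_path = directory / f"{stem}.json"
    tifffile.imwrite(img_path, stack, photometric='minisblack')
    tifffile.imwrite(lab_path, scene.labels.astype(np.uint16))
    write_json(meta_path, {"channels": names,
                           "pixel_size_um": scene.pixel_size_um,
                           "rng_seed": scene.rng_seed})
    return [img_path, lab_path, meta_path]


def read_scene(directory: Path, stem: str) -> ImageScene:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    stack = tifffile.imread(directory / f"{stem}.tif")
    if stack.ndim == 2:
        stack = stack[None]
    labels = tifffile.imread(directory / f"{stem}_labels.tif")
    channels = {n: stack[i].astype(float) for i, n in enumerate(meta["channels"])}
    return ImageScene(channels, labels.astype(np.uint16),
                      float(meta["pixel_size_um"]), int(meta["rng_seed"]))


def write_spectral_scene(scene: SpectralScene, directory: Path, stem: str) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{stem}.tif"
    lab_path = directory / f"{stem}_labels.tif"
    meta_path = directory / f"{stem}.json"
    tifffile.imwrite(img_path, np.moveaxis(scene.stack, 2, 0).astype(np.float32),
                     photometric='minisblack')
    tifffile.imwrite(lab_path, scene.labels.astype(np.uint16))
    write_json(meta_path, {"wavelengths_nm": list(map(float, scene.wavelengths_nm)),
                           "pixel_size_um": scene.pixel_size_um,
                           "rng_seed": scene.rng_seed})
    return [img_path, lab_path, meta_path]


def read_spectral_scene(directory: Path, stem: str) -> SpectralScene:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    stack = tifffile.imread(directory / f"{stem}.tif")
    labels = tifffile.imread(directory / f"{stem}_labels.tif")
    return SpectralScene(np.moveaxis(stack.astype(float), 0, 2),
                         np.asarray(meta["wavelengths_nm"], dtype=float),
                         labels.astype(np.uint16),
                         float(meta["pixel_size_um"]), int(meta["rng_seed"]))


def write_ground_truth(gt: GroundTruth, csv_path: Path, json_path: Path) -> None:
    gt.to_dataframe().to_csv(csv_path, index=False)
    params = {k: (list(v) if isinstance(v, tuple) else v)
              for k, v in gt.params.items()}
    write_json(json_path, params)


def write_profiles_csv(profiles: list[IntensityProfile], path: Path) -> None:
    """Long format: cell_id, channel, length_um, position, value."""
    rows = []
    for p in profiles:
        for pos, val in zip(p.positions, p.values):
            rows.append((p.cell_id, p.channel, p.length_um, pos, val))
    pd.DataFrame(rows, columns=["cell_id", "channel", "length_um",
                                "position", "value"]).to_csv(path, index=False)


def read_profiles_csv(path: Path) -> list[IntensityProfile]:
    df = pd.read_csv(path)
    required = {"cell_id", "channel", "length_um", "position", "value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"profile CSV missing columns "
                                 f"{sorted(required - set(df.columns))}")
    out = []
    for (cid, channel), sub in df.groupby(["cell_id", "channel"], sort=True):
        sub = sub.sort_values("position")
        out.append(IntensityProfile(
            cell_id=int(cid), channel=str(channel),
            positions=sub["position"].to_numpy(dtype=float),
            values=sub["value"].to_numpy(dtype=float),
            length_um=float(sub["length_um"].iloc[0]),
            native_step_um=float("nan"),
        ))
    return out


def write_mean_profile_csv(mean: MeanProfile, path: Path) -> None:
    pd.DataFrame({"position": mean.positions, "mean": mean.mean,
                  "sd": mean.sd, "n_cells": mean.n_cells}).to_csv(path, index=False)


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
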