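"""File formats: multipage TIFF stacks, JSON sidecars, YAML configs.

Raw strips are written as one multipage 16-bit TIFF per channel
(``strip_<channel>.tiff``) with a JSON sidecar carrying geometry, stage
positions and seed.  Phantoms and reconstructed volumes go to 32-bit float
multipage TIFF (Z pages) plus a sidecar with pitch/origin/ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .acquisition import AcquisitionGeometry, RawStrip
from .phantom import Phantom
from .reconstruct import Volume


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_strips(strips: dict[str, RawStrip], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, strip in strips.items():
        tifffile.imwrite(outdir / f"strip_{name}.tiff", strip.to_uint16())
        side = {
            "channel": name,
            "stage_x_um": strip.stage_x_um.tolist(),
            "geometry": _jsonable(vars(strip.geometry)),
            "seed": strip.seed,
            "noise": strip.noise,
            "saturated_pixels": strip.saturated_pixels,
            "meta": _jsonable(strip.meta),
        }
        (outdir / f"strip_{name}.json").write_text(json.dumps(side, indent=1))


def load_strip(outdir, channel: str) -> RawStrip:
    outdir = Path(outdir)
    frames = tifffile.imread(outdir / f"strip_{channel}.tiff").astype(np.float32)
    side = json.loads((outdir / f"strip_{channel}.json").read_text())
    g = side["geometry"]
    g["frame_shape"] = tuple(g["frame_shape"])
    geom = AcquisitionGeometry(**g)
    return RawStrip(frames=frames,
                    stage_x_um=np.asarray(side["stage_x_um"]),
                    geometry=geom, channel=channel, seed=side.get("seed"),
                    noise=side.get("noise", False),
                    saturated_pixels=side.get("saturated_pixels", 0),
                    meta=side.get("meta", {}))


def save_phantom(phantom: Phantom, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([phantom.fluor, phantom.shg]).astype(np.float32)
    tifffile.imwrite(path, stack)
    side = {
        "voxel_pitch_um": list(phantom.voxel_pitch_um),
        "surface_z_um": phantom.surface_z_um,
        "provenance": _jsonable(phantom.provenance),
        "truth": _jsonable(phantom.truth),
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_phantom(path) -> Phantom:
    path = Path(path)
    stack = tifffile.imread(path).astype(np.float64)
    side = json.loads(path.with_suffix(".json").read_text())
    truth = side.get("truth", {})
    for key in ("bead_centers_um", "nuclei_centers_um"):
        if key in truth:
            truth[key] = np.asarray(truth[key])
    return Phantom(fluor=stack[0], shg=stack[1],
                   voxel_pitch_um=tuple(side["voxel_pitch_um"]),
                   surface_z_um=side.get("surface_z_um", 0.0),
                   provenance=side.get("provenance", {}), truth=truth)


def save_volume(volume: Volume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    side = {
        "pitch_um": list(volume.pitch_um),
        "origin_um": list(volume.origin_um),
        "channel": volume.channel,
        "meta": _jsonable(volume.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_volume(path) -> Volume:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float32)
    side = json.loads(path.with_suffix(".json").read_text())
    return Volume(data=data, pitch_um=tuple(side["pitch_um"]),
                  origin_um=tuple(side["origin_um"]),
                  channel=side.get("channel", ""), meta=side.get("meta", {}))
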