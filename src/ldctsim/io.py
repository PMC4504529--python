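"""HDF5 container and PNG previews for maps, sinograms and images.

Each array type is stored as a single dataset with its scalar metadata in
HDF5 attributes; scan protocols and provenance travel with the data so a
downstream reconstruction or analysis never needs side information.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
from PIL import Image

from .config import DISPLAY_WINDOW
from .phantoms import AttenuationMap
from .recon import ReconImage
from .scanner import ScanProtocol, Sinogram

__all__ = [
    "save_map",
    "load_map",
    "save_sinogram",
    "load_sinogram",
    "save_image",
    "load_image",
    "write_png",
]


def save_map(amap: AttenuationMap, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("hu", data=amap.grid)
        d.attrs["pixel_size"] = amap.pixel_size
        d.attrs["fov"] = amap.fov
        d.attrs["kind"] = "attenuation_map"


def load_map(path) -> AttenuationMap:
    with h5py.File(path, "r") as f:
        d = f["hu"]
        return AttenuationMap(d[()], float(d.attrs["pixel_size"]))


def _protocol_json(protocol: ScanProtocol | None) -> str:
    return json.dumps(dataclasses.asdict(protocol)) if protocol else ""


def save_sinogram(sino: Sinogram, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("p", data=sino.values)
        d.attrs["bin_spacing"] = sino.bin_spacing
        d.attrs["mu_water"] = sino.mu_water
        d.attrs["protocol"] = _protocol_json(sino.protocol)
        d.attrs["meta"] = json.dumps(sino.meta)
        d.attrs["kind"] = "sinogram"


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["p"]
        proto_s = d.attrs["protocol"]
        protocol = ScanProtocol(**json.loads(proto_s)) if proto_s else None
        return Sinogram(
            d[()],
            float(d.attrs["bin_spacing"]),
            protocol=protocol,
            mu_water=float(d.attrs["mu_water"]),
            meta=json.loads(d.attrs["meta"]),
        )


def save_image(img: ReconImage, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("hu", data=img.grid)
        d.attrs["pixel_size"] = img.pixel_size
        d.attrs["kernel_name"] = img.kernel_name
        d.attrs["provenance"] = json.dumps(img.provenance)
        d.attrs["kind"] = "recon_image"


def load_image(path) -> ReconImage:
    with h5py.File(path, "r") as f:
        d = f["hu"]
        return ReconImage(
            d[()],
            float(d.attrs["pixel_size"]),
            kernel_name=str(d.attrs["kernel_name"]),
            provenance=json.loads(d.attrs["provenance"]),
        )


def write_png(
    grid_or_image, path, window: tuple[float, float] = DISPLAY_WINDOW
) -> None:
    """8-bit PNG preview of an HU array under a (width, center) display window.

    The default window (700/100 HU) is the usual angiography soft-tissue
    display setting.
    """
    grid = getattr(grid_or_image, "grid", grid_or_image)
    width, center = window
    lo, hi = center - width / 2.0, center + width / 2.0
    scaled = np.clip((np.asarray(grid) - lo) / (hi - lo), 0.0, 1.0)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="L").save(path)
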