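"""HDF5 / TIFF serialization of phantoms, image stacks and retrieved maps."""

from __future__ import annotations

import json
from typing import Tuple

import h5py
import numpy as np
import tifffile

from .images import ConcentrationMap, DetectorImage, ImageStack
from .phantom import OpticalProperties, VoxelPhantom

__all__ = [
    "save_phantom", "load_phantom",
    "save_stack", "load_stack",
    "save_concentration_map", "load_concentration_map",
    "save_detector_tiff", "load_detector_tiff",
]


def save_phantom(path, phantom: VoxelPhantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=phantom.labels, compression="gzip")
        f.attrs["voxel_size_mm"] = phantom.voxel_size
        f.attrs["exterior_n"] = phantom.exterior_n
        mats = {
            str(lab): {"mua": p.mua, "musp": p.musp, "g": p.g, "n": p.n}
            for lab, p in phantom.materials.items()
        }
        f.attrs["materials_json"] = json.dumps(mats)


def load_phantom(path) -> VoxelPhantom:
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        mats = {
            int(lab): OpticalProperties(**props)
            for lab, props in json.loads(f.attrs["materials_json"]).items()
        }
        return VoxelPhantom(labels, float(f.attrs["voxel_size_mm"]), mats,
                            float(f.attrs["exterior_n"]))


def save_stack(path, stack: ImageStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=stack.images, compression="gzip")
        f.create_dataset("positions_mm", data=stack.positions)
        f.attrs["center_index"] = stack.center_index
        f.attrs["wavelength_nm"] = stack.wavelength
        f.attrs["pixel_pitch_mm"] = stack.pixel_pitch
        f.attrs["provenance"] = stack.provenance


def load_stack(path) -> ImageStack:
    with h5py.File(path, "r") as f:
        return ImageStack(
            f["images"][...], f["positions_mm"][...],
            int(f.attrs["center_index"]), float(f.attrs["wavelength_nm"]),
            float(f.attrs["pixel_pitch_mm"]), str(f.attrs["provenance"]),
        )


def save_concentration_map(path, cmap: ConcentrationMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dye_uM", data=cmap.dye_uM, compression="gzip")
        f.create_dataset("inks_uM", data=cmap.inks_uM, compression="gzip")
        f.create_dataset("valid", data=cmap.valid.astype(np.uint8),
                         compression="gzip")
        f.attrs["pixel_pitch_mm"] = cmap.pixel_pitch


def load_concentration_map(path) -> ConcentrationMap:
    with h5py.File(path, "r") as f:
        return ConcentrationMap(
            f["dye_uM"][...], f["inks_uM"][...],
            f["valid"][...].astype(bool), float(f.attrs["pixel_pitch_mm"]),
        )


def save_detector_tiff(path, image: DetectorImage) -> None:
    """Write the exit-face image as a 32-bit float TIFF with metadata tags."""
    tifffile.imwrite(
        path, image.data.astype(np.float32),
        metadata={"pixel_pitch_mm": image.pixel_pitch,
                  "wavelength_nm": image.wavelength,
                  "n_photons": image.n_photons, "seed": image.seed},
    )


def load_detector_tiff(path) -> DetectorImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return DetectorImage(
        data, float(meta.get("pixel_pitch_mm", 1.0)),
        float(meta.get("wavelength_nm", 0.0)),
        int(meta.get("n_photons", 0)), int(meta.get("seed", 0)),
    )
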