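"""Reading and writing fields, label maps and per-cell tables.

Fields are stored as OME-TIFF (axes CZYX, channel names and physical
voxel sizes in the metadata) via :mod:`tifffile`; ground-truth label
volumes as plain TIFF stacks; tables as CSV with documented column
order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .acquisition import AcquisitionSpec, FieldImage, GroundTruth


def write_field(field: FieldImage, path: str | Path) -> Path:
    """Write a multi-channel field as OME-TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(field.channels)
    stack = np.stack([field.channels[c] for c in names]).astype(np.float32)
    spec = field.spec
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": spec.pixel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": spec.pixel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": spec.z_step,
            "PhysicalSizeZUnit": "µm",
        },
    )
    sidecar = {
        "genotype": field.genotype,
        "gene": field.gene,
        "field_index": field.field_index,
        "channels": names,
        "pixel_size_xy": spec.pixel_size_xy,
        "z_step": spec.z_step,
        "n_slices": spec.n_slices,
        "frame_shape": list(spec.frame_shape),
        "psf_sigma_xy": spec.psf_sigma_xy,
        "psf_sigma_z": spec.psf_sigma_z,
        "noise_read_sd": spec.noise_read_sd,
        "photon_scale": spec.photon_scale,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_field(path: str | Path) -> FieldImage:
    """Read a field written by :func:`write_field`."""
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if stack.ndim == 3:  # single channel
        stack = stack[None]
    spec = AcquisitionSpec(
        pixel_size_xy=meta["pixel_size_xy"],
        z_step=meta["z_step"],
        n_slices=meta["n_slices"],
        frame_shape=tuple(meta["frame_shape"]),
        psf_sigma_xy=meta["psf_sigma_xy"],
        psf_sigma_z=meta["psf_sigma_z"],
        noise_read_sd=meta["noise_read_sd"],
        photon_scale=meta["photon_scale"],
    )
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channels"])}
    return FieldImage(
        channels=channels,
        spec=spec,
        genotype=meta["genotype"],
        gene=meta["gene"],
        field_index=meta["field_index"],
    )


def write_ground_truth(truth: GroundTruth, directory: str | Path, stem: str) -> Path:
    """Write label volumes (16-bit TIFF) and the per-cell truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, vol in (
        ("cells", truth.cell_label_volume),
        ("nuclei", truth.nucleus_label_volume),
        ("mito", truth.mito_label_volume),
    ):
        tifffile.imwrite(
            directory / f"{stem}_{name}.tiff",
            vol.astype(np.uint16),
            photometric="minisblack",
        )
    truth.cells.to_csv(directory / f"{stem}_cells.csv", index=False)
    return directory


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write a 2D label map as 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    return path


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
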