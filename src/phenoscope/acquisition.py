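"""Domain types for calibrated multi-channel z-stack acquisitions.

Conventions used throughout the package:

* volumes are ``numpy`` arrays in ``(z, y, x)`` axis order;
* physical coordinates are in micrometres, with the centre of voxel
  ``(k, j, i)`` at ``((k + 0.5) * z_step, (j + 0.5) * pixel, (i + 0.5) * pixel)``;
* every stochastic operation takes a single integer seed and derives all
  of its random streams from it through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

LocalizationClass = Literal[
    "cytoplasmic", "nuclear", "punctate", "mitochondrial", "periphery"
]

LOCALIZATION_CLASSES: tuple[str, ...] = (
    "cytoplasmic",
    "nuclear",
    "punctate",
    "mitochondrial",
    "periphery",
)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Calibration and noise model of one confocal acquisition.

    Parameters
    ----------
    pixel_size_xy:
        Lateral calibration in μm/pixel. The default 0.1038 μm/px comes
        from the instrument calibration 60 px = 6.23 μm.
    z_step:
        Axial spacing between slices in μm.
    n_slices:
        Number of z planes per stack (30 in the source screen).
    frame_shape:
        ``(height, width)`` of each plane in pixels.
    psf_sigma_xy, psf_sigma_z:
        Standard deviations of the anisotropic Gaussian point-spread
        function, in μm. Zero disables blurring along that axis.
    noise_read_sd:
        Standard deviation of additive Gaussian read noise, in intensity
        units. Zero disables read noise.
    photon_scale:
        Photons detected per intensity unit; controls Poisson shot noise.
        ``None`` (or 0) disables shot noise.
    """

    pixel_size_xy: float = 0.1038
    z_step: float = 0.3
    n_slices: int = 30
    frame_shape: tuple[int, int] = (512, 512)
    psf_sigma_xy: float = 0.15
    psf_sigma_z: float = 0.45
    noise_read_sd: float = 1.5
    photon_scale: float | None = 100.0

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be at least 1")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 8:
            raise ValueError("frame_shape must be (height, width), each >= 8 px")
        for name in ("psf_sigma_xy", "psf_sigma_z", "noise_read_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.photon_scale is not None and self.photon_scale < 0:
            raise ValueError("photon_scale must be nonnegative or None")

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.n_slices, *self.frame_shape)

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        """Voxel edge lengths ``(dz, dy, dx)`` in μm."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³ (``pixel_size_xy² × z_step``)."""
        return self.pixel_size_xy**2 * self.z_step

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size ``(z, y, x)`` of the imaged volume in μm."""
        return (
            self.n_slices * self.z_step,
            self.frame_shape[0] * self.pixel_size_xy,
            self.frame_shape[1] * self.pixel_size_xy,
        )


@dataclass(frozen=True)
class CellSpec:
    """Geometry and fluorescence of one simulated yeast cell.

    ``center`` is the ``(z, y, x)`` position in μm; ``diameter`` the cell
    sphere diameter in μm. ``localization_class`` selects the GFP
    distribution; ``intensity_scale`` sets the cytoplasmic-equivalent
    brightness in camera units. ``tubule_params`` is
    ``(n_tubules, mean_length_um, radius_um)`` for mitochondrial cells;
    fewer, longer tubules at the same total length model network fusion.
    When ``mito_target_volume`` (μm³) is set, tubules of the configured
    length and radius are added until the rendered network's voxel
    volume reaches it — the injected volume is then exact despite
    tubule–tubule overlap — and ``n_tubules`` only seeds the start-point
    stratification.
    """

    center: tuple[float, float, float]
    diameter: float
    localization_class: str = "cytoplasmic"
    intensity_scale: float = 100.0
    n_puncta: int = 6
    tubule_params: tuple[int, float, float] = (5, 1.6, 0.28)
    mito_target_volume: float | None = None
    nucleus_diameter_fraction: float = 0.35

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.intensity_scale < 0:
            raise ValueError("intensity_scale must be nonnegative")
        if self.localization_class not in LOCALIZATION_CLASSES:
            raise ValueError(
                f"unknown localization_class {self.localization_class!r}; "
                f"expected one of {LOCALIZATION_CLASSES}"
            )
        if not 0 < self.nucleus_diameter_fraction < 1:
            raise ValueError("nucleus_diameter_fraction must be in (0, 1)")
        n_tub, length, radius = self.tubule_params
        if n_tub < 1 or length <= 0 or radius <= 0:
            raise ValueError("tubule_params must be (n>=1, length>0, radius>0)")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class GroundTruth:
    """Voxel-exact truth accompanying one synthetic field.

    Label volumes share the acquisition's shape; label ``k`` in
    ``nucleus_label_volume`` / ``mito_label_volume`` belongs to cell ``k``
    of ``cell_label_volume``. ``cells`` is a per-cell table with columns::

        label, class, center_z, center_y, center_x (px), diameter_um,
        intensity_scale, true_mean_gfp, true_mean_gfp_maxproj,
        true_mean_gfp_meanproj, cell_volume_um3, mito_volume_um3

    The ``true_mean_gfp*`` columns are means of the noise-free (post-PSF)
    GFP signal over the cell's own voxels / footprint, so estimators can
    be checked for bias independently of the noise realization.
    """

    cell_label_volume: np.ndarray
    nucleus_label_volume: np.ndarray
    mito_label_volume: np.ndarray
    cells: pd.DataFrame
    voxel_volume: float


@dataclass
class FieldImage:
    """One acquired field: named channel volumes plus acquisition metadata."""

    channels: dict[str, np.ndarray]
    spec: AcquisitionSpec
    genotype: str = ""
    gene: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        shapes = {ch: v.shape for ch, v in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel volumes must share one shape, got {shapes}")
        for ch, vol in self.channels.items():
            if np.any(vol < 0):
                raise ValueError(f"channel {ch!r} contains negative intensities")

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]
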