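"""Volumetric I/O, smoothing and profile extraction.

Maps live on a 3-D voxel lattice (NIfTI-1 on disk). An :class:`Atlas` labels
every voxel with a region id (0 = background) and assigns each region to a
compartment (cortex or subcortex); analyses are run per compartment, never
mixing the two. Zero is the background sentinel throughout: voxels with
value 0 are treated as outside the investigated area and excluded from
profiles, so maps where 0 is a legitimate value must be offset upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    AlignmentError,
    DimensionalityError,
    EmptyProfileError,
    FormatError,
    ParameterError,
)

__all__ = [
    "BrainVolume",
    "Atlas",
    "SpatialProfile",
    "read_volume",
    "write_volume",
    "smooth_volume",
    "extract_voxel_profile",
    "extract_region_profile",
]

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cortex", "subcortex")

#: full-width-at-half-maximum to Gaussian sigma conversion factor
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BrainVolume:
    """A 3-D scalar map with voxel geometry.

    Parameters
    ----------
    values
        3-D array of map values; 0 encodes background.
    voxel_size
        Edge lengths of a voxel in mm, one per axis.
    origin
        mm coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D array, got {self.values.ndim}-D "
                f"with shape {self.values.shape}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_coordinates(self, idx: np.ndarray) -> np.ndarray:
        """mm coordinates of integer voxel indices (n, 3)."""
        return np.asarray(idx, dtype=float) * np.array(self.voxel_size) + np.array(
            self.origin
        )


@dataclass
class Atlas:
    """A labeled parcellation volume plus its region table.

    ``labels`` assigns every voxel a region id (0 = background); ``regions``
    is a table with one row per region: region_id, compartment, centroid mm
    coordinates (x, y, z) and voxel count.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        required = {"region_id", "compartment", "x", "y", "z", "n_voxels"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ParameterError(f"region table missing columns: {sorted(missing)}")

    def region_ids(self, compartment: str) -> np.ndarray:
        _check_compartment(compartment)
        sel = self.regions[self.regions["compartment"] == compartment]
        return sel["region_id"].to_numpy()

    def centroids(self, compartment: str) -> np.ndarray:
        _check_compartment(compartment)
        sel = self.regions[self.regions["compartment"] == compartment]
        return sel[["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class SpatialProfile:
    """One value per spatial unit (voxel or region) for a single map."""

    unit_ids: np.ndarray
    values: np.ndarray
    compartment: str
    coordinates: np.ndarray
    granularity: str = "region"

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.unit_ids) != len(self.values):
            raise ParameterError("unit_ids and values length mismatch")
        if len(np.unique(self.unit_ids)) != len(self.unit_ids):
            raise ParameterError("unit_ids must be unique")

    def __len__(self) -> int:
        return len(self.values)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances between unit coordinates (mm)."""
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "compartment": self.compartment,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "z": self.coordinates[:, 2],
                "value": self.values,
            }
        )


def _check_compartment(compartment: str) -> None:
    if compartment not in COMPARTMENTS:
        raise ParameterError(
            f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}"
        )


def read_volume(path) -> BrainVolume:
    """Read a NIfTI volume into a :class:`BrainVolume`.

    Raises :class:`FormatError` if the file cannot be parsed and
    :class:`DimensionalityError` if the payload is not 3-D.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not parse {path} as a volume: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3-D volume, got {data.ndim}-D shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return BrainVolume(np.asarray(data, dtype=float), tuple(float(z) for z in zooms), origin)


def write_volume(vol: BrainVolume, path) -> None:
    """Write a :class:`BrainVolume` to NIfTI-1."""
    img = nib.Nifti1Image(vol.values.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def smooth_volume(vol: BrainVolume, fwhm_mm) -> BrainVolume:
    """Gaussian-smooth a volume with a per-axis FWHM given in mm.

    sigma (voxels) = fwhm / (2 sqrt(2 ln 2)) / voxel_size. A FWHM of zero on
    every axis is the identity. Boundaries use nearest-edge replication so a
    constant map stays constant.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ParameterError(f"fwhm must be non-negative, got {tuple(fwhm)}")
    if np.all(fwhm == 0):
        return BrainVolume(vol.values.copy(), vol.voxel_size, vol.origin)
    sigma_vox = fwhm * FWHM_TO_SIGMA / np.array(vol.voxel_size)
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="nearest")
    return BrainVolume(smoothed, vol.voxel_size, vol.origin)


def _align_to_atlas(vol: BrainVolume, atlas: Atlas) -> np.ndarray:
    """Return the volume's value array on the atlas grid.

    Shapes must match exactly, or differ by integer per-axis factors, in
    which case nearest-neighbor resampling is applied. Anything else is an
    alignment error: silent interpolation hides registration bugs.
    """
    vshape = np.array(vol.values.shape)
    ashape = np.array(atlas.labels.shape)
    if np.array_equal(vshape, ashape):
        return vol.values
    if np.all(vshape % ashape == 0):
        f = vshape // ashape
        return vol.values[:: f[0], :: f[1], :: f[2]]
    if np.all(ashape % vshape == 0):
        f = ashape // vshape
        return np.repeat(np.repeat(np.repeat(vol.values, f[0], 0), f[1], 1), f[2], 2)
    raise AlignmentError(
        f"volume shape {tuple(vshape)} is not integer-scale compatible with "
        f"atlas shape {tuple(ashape)}"
    )


def extract_voxel_profile(vol: BrainVolume, atlas: Atlas, compartment: str) -> SpatialProfile:
    """Voxel-wise profile for one compartment.

    Includes every voxel whose atlas label belongs to the compartment and
    whose value is nonzero (zero marks space outside the investigated area).
    Ordering is lexicographic in voxel index, so repeated runs agree.
    """
    _check_compartment(compartment)
    values = _align_to_atlas(vol, atlas)
    ids = atlas.region_ids(compartment)
    mask = np.isin(atlas.labels, ids) & (values != 0)
    idx = np.argwhere(mask)  # lexicographic (C-order) by construction
    if idx.size == 0:
        raise EmptyProfileError(
            f"no nonzero voxels in compartment {compartment!r}"
        )
    flat = np.ravel_multi_index(idx.T, atlas.labels.shape)
    coords = idx * np.array(atlas.voxel_size) + np.array(atlas.origin)
    return SpatialProfile(flat, values[mask], compartment, coords, granularity="voxel")


def extract_region_profile(vol: BrainVolume, atlas: Atlas, compartment: str) -> SpatialProfile:
    """Region-wise profile: mean of surviving (nonzero) voxels per region.

    Zero-valued voxels are excluded before averaging, not averaged in as
    zeros. Regions left with no surviving voxels are dropped with a warning.
    Coordinates are region centroids in mm from the atlas table.
    """
    _check_compartment(compartment)
    values = _align_to_atlas(vol, atlas)
    sel = atlas.regions[atlas.regions["compartment"] == compartment]
    if len(sel) == 0:
        raise EmptyProfileError(f"atlas has no regions in compartment {compartment!r}")
    ids, means, coords = [], [], []
    dropped = []
    for row in sel.itertuples(index=False):
        region_vals = values[(atlas.labels == row.region_id) & (values != 0)]
        if region_vals.size == 0:
            dropped.append(row.region_id)
            continue
        ids.append(row.region_id)
        means.append(float(region_vals.mean()))
        coords.append((row.x, row.y, row.z))
    if dropped:
        logger.warning(
            "dropped %d region(s) with no surviving voxels in %s: %s",
            len(dropped), compartment, dropped,
        )
    if not ids:
        raise EmptyProfileError(
            f"all regions empty after zero-exclusion in {compartment!r}"
        )
    return SpatialProfile(
        np.array(ids), np.array(means), compartment, np.array(coords), granularity="region"
    )
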