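"""Voxelized layered head models for CW photon-diffusion modelling.

A :class:`HeadModel` is a regular isotropic voxel grid (right-handed RAS
millimetres, 0-based indices, a voxel's position is its center) carrying an
integer tissue label per voxel and per-tissue optical properties per
wavelength.  Two parametric geometries stand in for an MRI-segmented head:

* ``slab`` — layers stacked below a flat top surface; used for unit tests
  because it admits an analytic semi-infinite diffusion oracle.
* ``hemisphere`` — a dome with concentric tissue shells; used for
  end-to-end runs with a curved scalp like a real forehead.

Layer order from the surface inward is scalp/skull, CSF, gray matter,
white matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DEFAULT_MU_A,
    DEFAULT_MU_S_PRIME,
    DEFAULT_REFRACTIVE_INDEX,
    TISSUE_CSF,
    TISSUE_GRAY,
    TISSUE_OUTSIDE,
    TISSUE_SCALP_SKULL,
    TISSUE_WHITE,
    WAVELENGTHS,
)

__all__ = ["HeadModel", "build_layered_head"]


class DimensionError(ValueError):
    """Grid cannot contain the requested layer structure."""


@dataclass
class HeadModel:
    """Regular voxel grid with tissue labels and optical properties.

    Parameters
    ----------
    tissue_label : ndarray of int, shape ``grid_shape``
        0=outside, 1=scalp/skull, 2=CSF, 3=gray, 4=white.
    voxel_size : float
        Isotropic voxel edge length in mm.
    mu_a, mu_s_prime : dict
        Maps ``(tissue_label, wavelength) -> coefficient`` in mm^-1.
    refractive_index : dict
        Maps ``tissue_label -> eta`` (dimensionless).
    geometry : str
        ``"slab"`` or ``"hemisphere"``; determines surface normals.
    """

    tissue_label: np.ndarray
    voxel_size: float
    mu_a: dict = field(default_factory=lambda: dict(DEFAULT_MU_A))
    mu_s_prime: dict = field(default_factory=lambda: dict(DEFAULT_MU_S_PRIME))
    refractive_index: dict = field(
        default_factory=lambda: {
            t: DEFAULT_REFRACTIVE_INDEX
            for t in (TISSUE_SCALP_SKULL, TISSUE_CSF, TISSUE_GRAY, TISSUE_WHITE)
        }
    )
    geometry: str = "slab"
    dome_center: np.ndarray | None = None
    dome_radius: float | None = None
    #: optional per-voxel absorption increment (mm^-1), added on top of the
    #: tissue table by :meth:`mu_a_volume`.  It perturbs the absorption
    #: (mass) term only — the diffusion coefficient keeps its baseline
    #: value, matching the linearization the absorption Jacobian computes.
    mu_a_perturbation: np.ndarray | None = None

    def __post_init__(self):
        self.tissue_label = np.ascontiguousarray(self.tissue_label, dtype=np.int16)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        present = set(np.unique(self.tissue_label)) - {TISSUE_OUTSIDE}
        for t in present:
            for w in WAVELENGTHS:
                for table, name in ((self.mu_a, "mu_a"), (self.mu_s_prime, "mu_s_prime")):
                    v = table.get((t, w))
                    if v is None:
                        raise ValueError(f"{name} missing for tissue {t} at {w} nm")
                    if v <= 0:
                        raise ValueError(f"{name}[{t},{w}] must be strictly positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.tissue_label.shape

    @property
    def inside(self) -> np.ndarray:
        """Boolean array, True where the voxel belongs to the head."""
        return self.tissue_label != TISSUE_OUTSIDE

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center positions in mm, C order."""
        nx, ny, nz = self.grid_shape
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return (idx + 0.5) * self.voxel_size

    def position_to_index(self, point) -> tuple[int, int, int]:
        """Voxel index containing a physical point (clipped to the grid)."""
        ijk = np.floor(np.asarray(point, float) / self.voxel_size).astype(int)
        return tuple(np.clip(ijk, 0, np.array(self.grid_shape) - 1))

    def mu_a_volume(self, wavelength: float) -> np.ndarray:
        """Per-voxel absorption map at one wavelength (0 outside)."""
        vol = self._property_volume(self.mu_a, wavelength)
        if self.mu_a_perturbation is not None:
            vol = vol + np.where(self.inside, self.mu_a_perturbation, 0.0)
        return vol

    def mu_s_prime_volume(self, wavelength: float) -> np.ndarray:
        return self._property_volume(self.mu_s_prime, wavelength)

    def _property_volume(self, table: dict, wavelength: float) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        for t in np.unique(self.tissue_label):
            if t == TISSUE_OUTSIDE:
                continue
            out[self.tissue_label == t] = table[(int(t), float(wavelength))]
        return out

    def inward_normal(self, point) -> np.ndarray:
        """Unit vector pointing from the surface into the head at `point`."""
        if self.geometry == "hemisphere":
            d = self.dome_center - np.asarray(point, float)
            n = np.linalg.norm(d)
            if n == 0:
                return np.array([0.0, 0.0, -1.0])
            return d / n
        return np.array([0.0, 0.0, -1.0])  # slab surface is the top z face

    def to_nifti(self):
        """Tissue labels as a NIfTI-1 image (int16, scaled affine)."""
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine[:3, 3] = 0.5 * self.voxel_size
        return nib.Nifti1Image(self.tissue_label.astype(np.int16), affine)

    def geometry_hash(self) -> str:
        """SHA-256 digest tying derived artifacts (Jacobians) to this model."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.tissue_label.tobytes())
        h.update(np.float64(self.voxel_size).tobytes())
        for key in sorted(self.mu_a):
            h.update(np.float64(self.mu_a[key]).tobytes())
            h.update(np.float64(self.mu_s_prime[key]).tobytes())
        return h.hexdigest()


def build_layered_head(
    grid_shape=(60, 60, 40),
    voxel_size: float = 2.0,
    layer_thicknesses=(10.0, 2.0, 6.0, None),
    geometry: str = "slab",
    dome_radius: float | None = None,
    mu_a: dict | None = None,
    mu_s_prime: dict | None = None,
) -> HeadModel:
    """Build a layered slab or hemispheric head model.

    Parameters
    ----------
    layer_thicknesses : sequence of 4 floats (mm)
        Thickness of scalp/skull, CSF, gray, white from the surface inward;
        ``None`` for the last entry means "fill the remaining depth".
        A zero thickness removes that layer.
    geometry : {"slab", "hemisphere"}
    dome_radius : float, optional
        Outer radius of the hemisphere (mm); default fits the grid.

    Raises
    ------
    DimensionError
        If the grid is too shallow/small to contain the requested layers.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    thick = list(layer_thicknesses)
    if len(thick) != 4:
        raise ValueError("expected 4 layer thicknesses (scalp/skull, CSF, gray, white)")
    if any(t is not None and t < 0 for t in thick):
        raise ValueError("layer thicknesses must be non-negative")
    finite = sum(t for t in thick if t is not None)

    nx, ny, nz = grid_shape
    h = float(voxel_size)
    labels = np.zeros(grid_shape, dtype=np.int16)
    layer_ids = (TISSUE_SCALP_SKULL, TISSUE_CSF, TISSUE_GRAY, TISSUE_WHITE)
    mu_a_table = dict(DEFAULT_MU_A)
    mu_s_table = dict(DEFAULT_MU_S_PRIME)
    if mu_a:
        mu_a_table.update(mu_a)
    if mu_s_prime:
        mu_s_table.update(mu_s_prime)

    if geometry == "slab":
        depth_extent = nz * h
        if finite >= depth_extent:
            raise DimensionError(
                f"layers need {finite} mm but slab depth is {depth_extent} mm"
            )
        zc = (np.arange(nz) + 0.5) * h
        depth = nz * h - zc  # depth of each voxel center below the top face
        bounds = _layer_bounds(thick, depth_extent)
        for lab, (d0, d1) in zip(layer_ids, bounds):
            sel = (depth > d0) & (depth <= d1)
            labels[:, :, sel] = lab
        head = HeadModel(labels, h, mu_a=mu_a_table, mu_s_prime=mu_s_table,
                         geometry="slab")
    elif geometry == "hemisphere":
        R = dome_radius if dome_radius is not None else min(nx * h, ny * h) / 2.0 - h
        if R <= 0 or finite >= R:
            raise DimensionError(f"layers need {finite} mm but dome radius is {R} mm")
        if 2 * R > nx * h + 1e-9 or 2 * R > ny * h + 1e-9 or R > nz * h + 1e-9:
            raise DimensionError("grid too small for the requested dome radius")
        center = np.array([nx * h / 2.0, ny * h / 2.0, 0.0])
        idx = np.indices(grid_shape).reshape(3, -1).T
        pos = (idx + 0.5) * h
        r = np.linalg.norm(pos - center, axis=1).reshape(grid_shape)
        depth = R - r  # distance inward from the spherical surface
        bounds = _layer_bounds(thick, R)
        for lab, (d0, d1) in zip(layer_ids, bounds):
            sel = (depth > d0) & (depth <= d1)
            labels[sel] = lab
        head = HeadModel(
            labels, h, mu_a=mu_a_table, mu_s_prime=mu_s_table,
            geometry="hemisphere", dome_center=center, dome_radius=R,
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return head


def _layer_bounds(thick, total_depth):
    """Depth intervals (d0, d1] for the four layers, surface inward."""
    bounds = []
    d = 0.0
    for t in thick:
        t = (total_depth - d) if t is None else t
        bounds.append((d, d + t))
        d += t
    return bounds
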