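"""Continuous-wave photon-diffusion forward model on the voxel grid.

Solves the CW diffusion equation

    -div( D grad Phi ) + mu_a Phi = q,   D = 1 / (3 (mu_a + mu_s'))

with a 7-point finite-volume discretization, harmonic-mean interface
diffusion coefficients, and Robin (partial-current) boundary conditions
derived from the tissue refractive index.  From the per-optode fluence
fields it assembles the channel x voxel Jacobian of optical density with
respect to absorption change (Rytov/adjoint construction) and the
array-sensitivity mask used to restrict statistical maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import WAVELENGTHS
from .headmodel import HeadModel
from .probe import ProbeLayout

__all__ = [
    "FluenceField",
    "Jacobian",
    "SensitivityMask",
    "DiffusionSolver",
    "solve_diffusion_cw",
    "compute_jacobian",
    "sensitivity_mask",
    "semi_infinite_fluence",
]


class SolverError(RuntimeError):
    """Linear solve failed to reach the requested residual."""


class GeometryError(ValueError):
    """Source/detector position incompatible with the head grid."""


def effective_reflection_coefficient(n: float) -> float:
    """Internal reflection parameter R_eff for a tissue-air interface.

    Polynomial fit in the relative refractive index n (Groenhuis-style);
    R_eff ~ 0.53 at n = 1.4.
    """
    return -1.440 * n**-2 + 0.710 / n + 0.668 + 0.0636 * n


@dataclass
class FluenceField:
    """CW fluence per voxel (mm^-2 per unit source power)."""

    values: np.ndarray  # full grid, zero outside the head
    source_location: np.ndarray
    wavelength: float


@dataclass
class SensitivityMask:
    """Voxels where aggregate array sensitivity is within `attenuation_factor`
    of its maximum (default 1000x)."""

    mask: np.ndarray  # boolean, full grid
    attenuation_factor: float
    aggregate: np.ndarray  # summed |J| per voxel, full grid

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self, voxel_size: float):
        import nibabel as nib

        affine = np.diag([voxel_size] * 3 + [1.0])
        affine[:3, 3] = 0.5 * voxel_size
        return nib.Nifti1Image(self.mask.astype(np.uint8), affine)


@dataclass
class Jacobian:
    """Channel x voxel sensitivity of OD to absorption change, per wavelength.

    ``matrices[wavelength]`` has shape (n_channels, n_inside); rows map
    delta-mu_a (mm^-1) on the inside voxels to dimensionless OD change.
    ``flat_indices`` gives each inside voxel's position in the raveled grid.
    """

    matrices: dict
    amplitudes: dict  # wavelength -> unperturbed channel amplitude
    flat_indices: np.ndarray
    grid_shape: tuple
    voxel_size: float
    geometry_hash: str

    @property
    def n_channels(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    @property
    def n_voxels(self) -> int:
        return self.flat_indices.size

    def embed(self, flat_values: np.ndarray) -> np.ndarray:
        """Scatter an (n_inside,) vector back into the full grid."""
        out = np.zeros(int(np.prod(self.grid_shape)))
        out[self.flat_indices] = flat_values
        return out.reshape(self.grid_shape)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["geometry_hash"] = self.geometry_hash
            f.attrs["voxel_size"] = self.voxel_size
            f.attrs["grid_shape"] = self.grid_shape
            f.create_dataset("flat_indices", data=self.flat_indices)
            for w in self.matrices:
                g = f.create_group(f"wavelength_{w:g}")
                g.create_dataset("J", data=self.matrices[w])
                g.create_dataset("amplitude", data=self.amplitudes[w])

    @classmethod
    def load_hdf5(cls, path) -> "Jacobian":
        import h5py

        with h5py.File(path, "r") as f:
            matrices, amplitudes = {}, {}
            for name in f:
                if name.startswith("wavelength_"):
                    w = float(name.split("_", 1)[1])
                    matrices[w] = f[name]["J"][()]
                    amplitudes[w] = f[name]["amplitude"][()]
            return cls(
                matrices,
                amplitudes,
                f["flat_indices"][()],
                tuple(f.attrs["grid_shape"]),
                float(f.attrs["voxel_size"]),
                str(f.attrs["geometry_hash"]),
            )


class DiffusionSolver:
    """Finite-volume CW diffusion operator for one head model and wavelength.

    The sparse SPD system is assembled once; each point-source solve runs
    preconditioned conjugate gradients to a 1e-10 relative residual.
    """

    def __init__(self, head: HeadModel, wavelength: float, rtol: float = 1e-10):
        self.head = head
        self.wavelength = float(wavelength)
        self.rtol = rtol
        self._assemble()

    def _assemble(self):
        head, w = self.head, self.wavelength
        h = head.voxel_size
        inside = head.inside
        n = int(inside.sum())
        if n == 0:
            raise GeometryError("head model has no tissue voxels")
        self.n_unknowns = n
        flat_inside = inside.ravel()
        self.flat_indices = np.flatnonzero(flat_inside)
        unknown = -np.ones(flat_inside.size, dtype=np.int64)
        unknown[self.flat_indices] = np.arange(n)
        self._unknown = unknown

        mu_a = head.mu_a_volume(w).ravel()[self.flat_indices]
        mu_sp = head.mu_s_prime_volume(w).ravel()[self.flat_indices]
        # D uses the baseline (tissue-table) absorption: a voxel-level
        # mu_a_perturbation enters the mass term only (see HeadModel)
        mu_a_base = head._property_volume(head.mu_a, w).ravel()[self.flat_indices]
        D = 1.0 / (3.0 * (mu_a_base + mu_sp))

        eta = np.empty(n)
        labels = head.tissue_label.ravel()[self.flat_indices]
        for t in np.unique(labels):
            eta[labels == t] = head.refractive_index[int(t)]
        reff = effective_reflection_coefficient(eta)
        A_refl = (1.0 + reff) / (1.0 - reff)

        shape = head.grid_shape
        strides = (shape[1] * shape[2], shape[2], 1)
        diag = mu_a.copy()
        rows, cols, vals = [], [], []
        ijk = np.array(np.unravel_index(self.flat_indices, shape)).T

        for axis in range(3):
            for sign in (1, -1):
                nb_ijk = ijk.copy()
                nb_ijk[:, axis] += sign
                in_grid = (nb_ijk[:, axis] >= 0) & (nb_ijk[:, axis] < shape[axis])
                nb_flat = (np.clip(nb_ijk, 0, np.array(shape) - 1) * strides).sum(axis=1)
                nb_unknown = np.where(in_grid, unknown[nb_flat], -1)
                interior = nb_unknown >= 0
                # interior face: harmonic-mean coupling
                Dn = D[nb_unknown[interior]]
                Df = 2.0 * D[interior] * Dn / (D[interior] + Dn)
                diag[interior] += Df / h**2
                rows.append(np.flatnonzero(interior))
                cols.append(nb_unknown[interior])
                vals.append(-Df / h**2)
                # boundary face: Robin partial-current outflow
                bnd = ~interior
                diag[bnd] += 1.0 / (h * (2.0 * A_refl[bnd] + h / (2.0 * D[bnd])))

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        A = sp.coo_matrix(
            (np.concatenate([vals, diag]),
             (np.concatenate([rows, np.arange(n)]),
              np.concatenate([cols, np.arange(n)]))),
            shape=(n, n),
        ).tocsr()
        self.matrix = A
        self._precond = spla.LinearOperator(
            (n, n), matvec=lambda x, d=1.0 / diag: d * x
        )
        self._D = D
        self._mu_a = mu_a
        self._mu_sp = mu_sp

    # -- source handling -------------------------------------------------

    def transport_mean_free_path(self, point) -> float:
        """1/(mu_a + mu_s') of the tissue at/nearest to `point` (mm)."""
        u = self._nearest_unknown(point)
        return float(1.0 / (self._mu_a[u] + self._mu_sp[u]))

    def interior_source_point(self, optode_position) -> np.ndarray:
        """Optode position moved one transport mean free path into the head."""
        p = np.asarray(optode_position, float)
        z0 = self.transport_mean_free_path(p)
        return p + z0 * self.head.inward_normal(p)

    def _nearest_unknown(self, point) -> int:
        i, j, k = self.head.position_to_index(point)
        flat = int(np.ravel_multi_index((i, j, k), self.head.grid_shape))
        u = self._unknown[flat]
        if u >= 0:
            return int(u)
        centers = (np.array(np.unravel_index(self.flat_indices, self.head.grid_shape)).T + 0.5) * self.head.voxel_size
        return int(np.argmin(np.linalg.norm(centers - np.asarray(point, float), axis=1)))

    def _trilinear(self, point):
        """Trilinear weights of `point` over inside voxels (renormalized)."""
        h = self.head.voxel_size
        p = np.asarray(point, float) / h - 0.5
        base = np.floor(p).astype(int)
        frac = p - base
        shape = self.head.grid_shape
        us, ws = [], []
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ijk = base + (dx, dy, dz)
                    if np.any(ijk < 0) or np.any(ijk >= shape):
                        continue
                    wgt = (
                        (frac[0] if dx else 1 - frac[0])
                        * (frac[1] if dy else 1 - frac[1])
                        * (frac[2] if dz else 1 - frac[2])
                    )
                    u = self._unknown[int(np.ravel_multi_index(tuple(ijk), shape))]
                    if u >= 0 and wgt > 0:
                        us.append(int(u))
                        ws.append(wgt)
        if not us:
            raise GeometryError(f"point {point} has no head tissue around it")
        ws = np.asarray(ws)
        return np.asarray(us), ws / ws.sum()

    def solve(self, source_point, from_optode: bool = True) -> FluenceField:
        """Fluence for a unit point source.

        With ``from_optode=True`` the source is first moved one transport
        mean free path along the inward surface normal (standard placement
        of the reduced isotropic source for a surface-coupled fiber).
        """
        p = np.asarray(source_point, float)
        h = self.head.voxel_size
        if np.any(p < -h) or np.any(p > (np.array(self.head.grid_shape) + 1) * h):
            raise GeometryError(f"source {p} lies outside the grid")
        if from_optode:
            p = self.interior_source_point(p)
        us, ws = self._trilinear(p)
        b = np.zeros(self.n_unknowns)
        b[us] = ws / h**3
        x, info = spla.cg(
            self.matrix, b, rtol=self.rtol, atol=0.0, maxiter=5000, M=self._precond
        )
        if info != 0:
            res = np.linalg.norm(self.matrix @ x - b) / np.linalg.norm(b)
            raise SolverError(f"CG did not converge (info={info}, residual={res:.2e})")
        full = np.zeros(int(np.prod(self.head.grid_shape)))
        full[self.flat_indices] = np.maximum(x, 0.0)
        return FluenceField(full.reshape(self.head.grid_shape), p, self.wavelength)

    def evaluate(self, field: FluenceField, point) -> float:
        """Trilinear interpolation of a fluence field at a physical point."""
        us, ws = self._trilinear(point)
        return float(field.values.ravel()[self.flat_indices[us]] @ ws)


def solve_diffusion_cw(head: HeadModel, source, wavelength: float) -> FluenceField:
    """One-off CW diffusion solve (see :class:`DiffusionSolver`)."""
    return DiffusionSolver(head, wavelength).solve(source)


def compute_jacobian(
    head: HeadModel, layout: ProbeLayout, wavelengths=None
) -> Jacobian:
    """Adjoint (Rytov) channel x voxel sensitivity matrices.

    For channel (s, d): ``J[ch, v] = Phi_s(v) * Phi_d(v) * h^3 / A_sd`` where
    Phi_d is obtained by reciprocity (detector treated as a source) and
    A_sd is the unperturbed channel amplitude, so a uniform absorption
    increase of ``dmu`` over the photon paths produces ``J @ dmu`` of OD
    increase.
    """
    if wavelengths is None:
        wavelengths = layout.wavelengths
    h = head.voxel_size
    matrices, amplitudes = {}, {}
    ghash = None
    for w in wavelengths:
        solver = DiffusionSolver(head, w)
        src_fields = [solver.solve(p) for p in layout.source_positions]
        det_fields = [solver.solve(p) for p in layout.detector_positions]
        det_points = [
            solver.interior_source_point(p) for p in layout.detector_positions
        ]
        flat = solver.flat_indices
        J = np.empty((layout.n_channels, flat.size))
        A = np.empty(layout.n_channels)
        for c, (s, d) in enumerate(layout.channels):
            phi_s = src_fields[s].values.ravel()[flat]
            phi_d = det_fields[d].values.ravel()[flat]
            A[c] = solver.evaluate(src_fields[s], det_points[d])
            if A[c] <= 0:
                raise SolverError(f"non-positive amplitude for channel {c}")
            J[c] = phi_s * phi_d * h**3 / A[c]
        matrices[float(w)] = J
        amplitudes[float(w)] = A
        ghash = ghash or head.geometry_hash()
    return Jacobian(
        matrices, amplitudes, solver.flat_indices, head.grid_shape, h, ghash
    )


def sensitivity_mask(jac: Jacobian, attenuation_factor: float = 1000.0) -> SensitivityMask:
    """Voxels whose aggregate sensitivity is >= max / attenuation_factor.

    Aggregate sensitivity is the channel-summed |J| averaged over the two
    wavelengths.  `attenuation_factor` = 1 keeps only the peak voxel(s).
    """
    if attenuation_factor < 1.0:
        raise ValueError("attenuation_factor must be >= 1")
    agg_flat = np.mean(
        [np.abs(J).sum(axis=0) for J in jac.matrices.values()], axis=0
    )
    full = jac.embed(agg_flat)
    mask = full >= full.max() / attenuation_factor
    mask &= full > 0
    return SensitivityMask(mask, float(attenuation_factor), full)


def semi_infinite_fluence(
    rho, z, mu_a: float, mu_s_prime: float, n: float = 1.4
) -> np.ndarray:
    """Analytic CW fluence in a homogeneous semi-infinite medium.

    Extrapolated-boundary Green's function for a unit point source coupled
    at the origin of the surface (z measured into the medium, rho lateral,
    both mm):

        Phi = (4 pi D)^-1 [ exp(-mu_eff r1)/r1 - exp(-mu_eff r2)/r2 ]

    with the reduced source at depth z0 = 1/(mu_a + mu_s'), its image at
    -(z0 + 2 zb), zb = 2 A D, and mu_eff = sqrt(3 mu_a (mu_a + mu_s')).
    """
    rho = np.asarray(rho, float)
    z = np.asarray(z, float)
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    z0 = 1.0 / (mu_a + mu_s_prime)
    reff = effective_reflection_coefficient(n)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    mu_eff = np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))
    r1 = np.sqrt(rho**2 + (z - z0) ** 2)
    r2 = np.sqrt(rho**2 + (z + z0 + 2 * zb) ** 2)
    return (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4 * np.pi * D)
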