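"""Regularized tomographic inversion and spectral unmixing.

Channel OD time series are mapped to voxel absorption changes per
wavelength with a minimum-norm Tikhonov solution

    x = J^T (J J^T + alpha * tr(J J^T)/n_ch * I)^-1 y

(the "energy minimization" inverse: among all absorption images exactly
consistent with the data in the regularized sense, the one of least
norm).  The Cholesky factorization of the regularized Gram matrix is
computed once and reused across time samples.  Absorption movies at the
two wavelengths are then unmixed voxel-by-voxel into O2Hb/HHb via the
pinned extinction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .constants import extinction_matrix
from .forward import Jacobian, SensitivityMask
from .preprocess import ODSeries

__all__ = ["AbsorptionMovie", "HbMovie", "invert", "unmix"]


@dataclass
class AbsorptionMovie:
    """Voxel absorption changes (mm^-1) per wavelength over time.

    Arrays are stored over the head's inside voxels (see `flat_indices`);
    entries outside the sensitivity mask are exactly zero.
    """

    delta_mu_a: dict  # wavelength -> (n_inside, n_time)
    regularization: float
    mask: SensitivityMask
    flat_indices: np.ndarray
    grid_shape: tuple
    voxel_size: float
    sampling_rate: float


@dataclass
class HbMovie:
    """Voxel O2Hb / HHb concentration changes (uM) over time."""

    o2hb: np.ndarray  # (n_inside, n_time)
    hhb: np.ndarray
    mask: SensitivityMask
    flat_indices: np.ndarray
    grid_shape: tuple
    voxel_size: float
    sampling_rate: float

    def embed(self, flat_values: np.ndarray) -> np.ndarray:
        """Scatter an (n_inside,) vector into the full voxel grid."""
        out = np.zeros(int(np.prod(self.grid_shape)))
        out[self.flat_indices] = flat_values
        return out.reshape(self.grid_shape)

    def voxel_positions(self) -> np.ndarray:
        """(n_inside, 3) voxel-center positions in mm."""
        return (
            np.array(np.unravel_index(self.flat_indices, self.grid_shape)).T + 0.5
        ) * self.voxel_size

    def to_nifti(self):
        """4-D NIfTI of the O2Hb movie (x, y, z, t)."""
        import nibabel as nib

        nt = self.o2hb.shape[1]
        vol = np.zeros(int(np.prod(self.grid_shape)) * nt).reshape(-1, nt)
        vol[self.flat_indices] = self.o2hb
        vol = vol.reshape(*self.grid_shape, nt)
        affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine[:3, 3] = 0.5 * self.voxel_size
        return nib.Nifti1Image(vol.astype(np.float32), affine)


def invert(
    jac: Jacobian,
    od: ODSeries,
    alpha: float = 0.01,
    mask: SensitivityMask | None = None,
) -> AbsorptionMovie:
    """Minimum-norm Tikhonov inversion of channel OD into voxel absorption.

    Channels flagged bad in `od` are excluded (their Jacobian rows are
    dropped).  `alpha` scales the identity regularizer relative to the
    mean eigenvalue of J J^T; the factorization is reused across all time
    samples.  Voxels outside the sensitivity `mask` (computed at the
    default 1000x attenuation if not given) are zeroed.
    """
    from .forward import sensitivity_mask as _make_mask

    if alpha <= 0:
        raise ValueError("alpha must be positive")
    good = [c for c in range(jac.n_channels) if c not in set(od.bad_channels)]
    if not good:
        raise ValueError("all channels are flagged bad")
    if mask is None:
        mask = _make_mask(jac)
    mask_flat = mask.mask.ravel()[jac.flat_indices]

    movies = {}
    for iw, w in enumerate(sorted(jac.matrices)):
        J = jac.matrices[w][good]
        y = od.od[iw][good]
        G = J @ J.T
        reg = alpha * np.trace(G) / G.shape[0]
        cho = scipy.linalg.cho_factor(G + reg * np.eye(G.shape[0]))
        x = J.T @ scipy.linalg.cho_solve(cho, y)
        x[~mask_flat] = 0.0
        movies[w] = x
    return AbsorptionMovie(
        movies, float(alpha), mask, jac.flat_indices, jac.grid_shape,
        jac.voxel_size, od.sampling_rate,
    )


def unmix(movie: AbsorptionMovie, extinction: np.ndarray | None = None) -> HbMovie:
    """Spectral unmixing of two-wavelength absorption into O2Hb/HHb (uM).

    Solves per voxel and sample ``[dmu_a(690); dmu_a(830)] = E [dO2Hb; dHHb]``
    with E the pinned extinction matrix (mm^-1 per uM).
    """
    wavelengths = sorted(movie.delta_mu_a)
    if len(wavelengths) != 2:
        raise ValueError("unmixing needs absorption at exactly two wavelengths")
    E = extinction_matrix(wavelengths) if extinction is None else np.asarray(extinction)
    if abs(np.linalg.det(E)) < 1e-18:
        raise ValueError("extinction matrix is singular")
    Einv = np.linalg.inv(E)
    stacked = np.stack([movie.delta_mu_a[w] for w in wavelengths])  # (2, nv, nt)
    conc = np.einsum("cw,wvt->cvt", Einv, stacked)
    return HbMovie(
        conc[0], conc[1], movie.mask, movie.flat_indices, movie.grid_shape,
        movie.voxel_size, movie.sampling_rate,
    )
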