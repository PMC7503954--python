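import copy

import numpy as np
import pytest
import scipy.ndimage as ndi

from nirdot.forward import (
    DiffusionSolver,
    GeometryError,
    compute_jacobian,
    semi_infinite_fluence,
    sensitivity_mask,
)
from nirdot.probe import ProbeLayout

SRC = np.array([31.0, 35.0, 60.0])  # on the homogeneous slab's top surface


@pytest.fixture(scope="module")
def homog_solver(homog_slab):
    return DiffusionSolver(homog_slab, 690.0)


@pytest.fixture(scope="module")
def homog_field(homog_solver):
    return homog_solver.solve(SRC)


def test_fluence_matches_semi_infinite_greens_function(homog_solver, homog_field):
    """Numerical fluence vs extrapolated-boundary analytic solution within
    10% over 10-40 mm lateral separations.  Offsets are voxel-center
    aligned so the comparison probes the solver, not trilinear
    interpolation between cells."""
    for rho in (10.0, 14.0, 20.0, 24.0, 30.0, 34.0, 40.0):
        for depth in (1.0, 3.0):
            num = homog_solver.evaluate(homog_field, SRC + [rho, 0.0, -depth])
            ana = semi_infinite_fluence(rho, depth, 0.01, 1.0)
            assert abs(num / ana - 1.0) < 0.10, (rho, depth, num / ana)


def test_fluence_nonnegative_and_decays_along_ray(homog_solver, homog_field):
    assert np.all(homog_field.values >= 0)
    vals = [
        homog_solver.evaluate(homog_field, SRC + [rho, 0.0, -3.0])
        for rho in np.arange(6.0, 40.0, 2.0)
    ]
    assert np.all(np.diff(vals) < 0)


def test_absorption_increase_decreases_fluence(homog_slab, homog_solver, homog_field):
    doubled = copy.deepcopy(homog_slab)
    for w in (690.0, 830.0):
        doubled.mu_a[(4, w)] = 0.02
    f2 = DiffusionSolver(doubled, 690.0).solve(SRC)
    # compare everywhere at least 5 mm from the source
    pos = homog_slab.voxel_centers()
    far = np.linalg.norm(pos - homog_field.source_location, axis=1) >= 5.0
    a = homog_field.values.ravel()[far]
    b = f2.values.ravel()[far]
    sel = a > 0
    assert np.all(b[sel] < a[sel])


def test_solve_satisfies_discrete_diffusion_equation(homog_solver, homog_field):
    """The returned fluence solves the discrete system to the stated
    tolerance, hence scaling the source power by c scales fluence by c."""
    x = homog_field.values.ravel()[homog_solver.flat_indices]
    us, ws = homog_solver._trilinear(
        homog_solver.interior_source_point(SRC)
    )
    b = np.zeros(homog_solver.n_unknowns)
    b[us] = ws / homog_solver.head.voxel_size**3
    res = np.linalg.norm(homog_solver.matrix @ x - b) / np.linalg.norm(b)
    assert res < 1e-8
    # determinism: an identical solve reproduces the field
    f2 = homog_solver.solve(SRC)
    assert np.allclose(f2.values, homog_field.values, rtol=1e-10, atol=0)


def test_source_outside_grid_rejected(homog_solver):
    with pytest.raises(GeometryError):
        homog_solver.solve([500.0, 0.0, 0.0])


def test_jacobian_rows_nonnegative_with_banana_maximum(slab_jacobian, slab_layout):
    for w, J in slab_jacobian.matrices.items():
        assert np.all(J >= -1e-15)
    shape = slab_jacobian.grid_shape
    for c, (s, d) in enumerate(slab_layout.channels):
        row = slab_jacobian.matrices[690.0][c]
        v = slab_jacobian.flat_indices[np.argmax(row)]
        x = (np.unravel_index(v, shape)[0] + 0.5) * slab_jacobian.voxel_size
        x_s = slab_layout.source_positions[s][0]
        x_d = slab_layout.detector_positions[d][0]
        assert min(x_s, x_d) <= x <= max(x_s, x_d)


def test_longer_channels_are_more_brain_sensitive(slab_jacobian, layered_slab):
    """The 30 mm channel's |J| mass in gray matter exceeds the 14 mm one's."""
    labels = layered_slab.tissue_label.ravel()[slab_jacobian.flat_indices]
    fracs = []
    for c in (0, 1):
        row = np.abs(slab_jacobian.matrices[690.0][c])
        fracs.append(row[labels == 3].sum() / row.sum())
    assert fracs[1] > fracs[0]


def test_jacobian_matches_perturbation_oracle(layered_slab, slab_layout, slab_jacobian):
    """Brute-force mu_a perturbation: recomputed DC amplitude change agrees
    with the adjoint row within 5% on high-sensitivity voxels."""
    jac = slab_jacobian
    eps = 1e-4
    agg = np.abs(jac.matrices[690.0]).sum(axis=0)
    mask = sensitivity_mask(jac)
    masked = mask.mask.ravel()[jac.flat_indices]
    candidates = [v for v in np.argsort(agg)[-400::79] if masked[v]]
    assert candidates
    for vi in candidates:
        pert = np.zeros(jac.grid_shape)
        pert.ravel()[jac.flat_indices[vi]] = eps
        h2 = copy.deepcopy(layered_slab)
        h2.mu_a_perturbation = pert
        solver = DiffusionSolver(h2, 690.0)
        field = solver.solve(slab_layout.source_positions[0])
        for c, (_, d) in enumerate(slab_layout.channels):
            det = solver.interior_source_point(slab_layout.detector_positions[d])
            dod_fd = -np.log(solver.evaluate(field, det) / jac.amplitudes[690.0][c])
            dod_adj = jac.matrices[690.0][c, vi] * eps
            if dod_fd > 1e-12:
                assert abs(dod_adj / dod_fd - 1.0) < 0.05


def test_zero_absorption_change_gives_zero_od(slab_jacobian):
    dmu = np.zeros(slab_jacobian.n_voxels)
    assert np.all(slab_jacobian.matrices[690.0] @ dmu == 0.0)


def test_reciprocity_of_source_detector_swap(layered_slab, slab_layout, slab_jacobian):
    swapped = ProbeLayout(
        [slab_layout.detector_positions[1]],
        [slab_layout.source_positions[0]],
        {},
        [(0, 0)],
    )
    jac_sw = compute_jacobian(layered_slab, swapped, wavelengths=(690.0,))
    a = slab_jacobian.matrices[690.0][1]
    b = jac_sw.matrices[690.0][0]
    assert np.linalg.norm(a - b) / np.linalg.norm(a) < 1e-6


def test_sensitivity_mask_semantics(slab_jacobian):
    m1 = sensitivity_mask(slab_jacobian, attenuation_factor=1.0)
    agg = m1.aggregate
    assert np.array_equal(np.flatnonzero(m1.mask.ravel()),
                          np.flatnonzero(agg.ravel() >= agg.max()))
    m_inf = sensitivity_mask(slab_jacobian, attenuation_factor=1e12)
    assert m_inf.mask.sum() == (agg > 0).sum()
    with pytest.raises(ValueError):
        sensitivity_mask(slab_jacobian, attenuation_factor=0.5)


def test_default_mask_is_contiguous_under_the_array(slab_jacobian):
    m = sensitivity_mask(slab_jacobian)
    _, n_comp = ndi.label(m.mask)
    assert n_comp == 1
    assert m.mask[:, :, 0].sum() == 0  # no voxels on the far side of the slab


def test_jacobian_hdf5_roundtrip(tmp_path, slab_jacobian):
    p = tmp_path / "jac.h5"
    slab_jacobian.save_hdf5(p)
    from nirdot.forward import Jacobian

    back = Jacobian.load_hdf5(p)
    assert back.geometry_hash == slab_jacobian.geometry_hash
    for w in slab_jacobian.matrices:
        assert np.array_equal(back.matrices[w], slab_jacobian.matrices[w])
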