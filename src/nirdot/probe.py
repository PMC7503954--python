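"""Probe geometry: optode layouts, fiducial alignment, surface projection.

The default layout emulates a prefrontal array of 15 dual-wavelength
sources and 15 detectors (a 16th source exists in the instrument's
multiplexing cycle but cannot be resolved and is never placed).  Channels
are all source-detector pairs whose separation falls in a configured
admissible range, 10-45 mm by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import WAVELENGTHS
from .headmodel import HeadModel

__all__ = [
    "ProbeLayout",
    "RigidTransform",
    "default_prefrontal_layout",
    "fiducial_align",
    "apply_transform",
    "project_optodes_to_surface",
    "fit_layout_to_head",
]


class DegenerateGeometryError(ValueError):
    """Fiducials are collinear (or otherwise unusable for alignment)."""


class CouplingError(RuntimeError):
    """An optode could not be coupled to the head surface."""


@dataclass
class RigidTransform:
    """Rotation + translation, applied as ``R @ p + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det=+1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.rotation.T + self.translation
        return out if np.ndim(points) == 2 else out[0]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class ProbeLayout:
    """Source/detector 3-D positions with fiducials and derived channels."""

    source_positions: np.ndarray
    detector_positions: np.ndarray
    fiducials: dict = field(default_factory=dict)
    channels: list = field(default_factory=list)
    wavelengths: tuple = WAVELENGTHS

    def __post_init__(self):
        self.source_positions = np.atleast_2d(
            np.asarray(self.source_positions, float)
        )
        self.detector_positions = np.atleast_2d(
            np.asarray(self.detector_positions, float)
        )
        self.channels = [(int(s), int(d)) for s, d in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def sd_distances(self) -> np.ndarray:
        """Per-channel source-detector separation (mm)."""
        return np.array(
            [
                np.linalg.norm(
                    self.source_positions[s] - self.detector_positions[d]
                )
                for s, d in self.channels
            ]
        )

    def with_channels_in_range(self, sd_range=(10.0, 45.0)) -> "ProbeLayout":
        """Rebuild the channel list as all SD pairs within `sd_range` mm."""
        lo, hi = sd_range
        chans = [
            (s, d)
            for s in range(len(self.source_positions))
            for d in range(len(self.detector_positions))
            if lo
            <= np.linalg.norm(self.source_positions[s] - self.detector_positions[d])
            <= hi
        ]
        return replace(self, channels=chans)

    def to_json(self, path) -> None:
        payload = {
            "source_positions": self.source_positions.tolist(),
            "detector_positions": self.detector_positions.tolist(),
            "fiducials": {k: list(map(float, v)) for k, v in self.fiducials.items()},
            "channels": [list(c) for c in self.channels],
            "wavelengths": list(self.wavelengths),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ProbeLayout":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["source_positions"], float),
            np.asarray(d["detector_positions"], float),
            {k: np.asarray(v, float) for k, v in d["fiducials"].items()},
            [tuple(c) for c in d["channels"]],
            tuple(d["wavelengths"]),
        )


def default_prefrontal_layout(sd_range=(10.0, 45.0)) -> ProbeLayout:
    """15-source / 15-detector interleaved planar array, centered at origin.

    Sources sit on a 5x3 lattice (20 mm pitch), detectors on the same
    lattice shifted by (10, 10) mm, giving nearest SD separations of
    ~14 mm and many overlapping channels out to 45 mm.  Fiducials are
    nominal digitizer-frame landmarks.  The array lies in the z=0 plane;
    use :func:`fit_layout_to_head` to drape it on a head model.
    """
    xs = np.arange(-40.0, 41.0, 20.0)
    ys = np.arange(-20.0, 21.0, 20.0)
    sources = np.array([[x, y, 0.0] for y in ys for x in xs])
    detectors = sources + np.array([10.0, 10.0, 0.0])
    fiducials = {
        "nasion": np.array([0.0, 90.0, -40.0]),
        "left_preauricular": np.array([-80.0, 0.0, -40.0]),
        "right_preauricular": np.array([80.0, 0.0, -40.0]),
    }
    layout = ProbeLayout(sources, detectors, fiducials, [])
    return layout.with_channels_in_range(sd_range)


def fiducial_align(measured_fiducials, template_fiducials) -> RigidTransform:
    """Least-squares rigid transform mapping measured to template fiducials.

    Closed-form Procrustes: centroids are matched and the rotation comes
    from the SVD of the 3x3 cross-covariance; no scaling.  Exact when the
    two fiducial triangles are congruent.

    Parameters
    ----------
    measured_fiducials, template_fiducials : (3, 3) arrays or dicts
        Three corresponding non-collinear points (dicts are matched by key).
    """
    if isinstance(measured_fiducials, dict) and isinstance(template_fiducials, dict):
        keys = sorted(set(measured_fiducials) & set(template_fiducials))
        if len(keys) != 3:
            raise ValueError("need three common named fiducials")
        A = np.array([measured_fiducials[k] for k in keys], float)
        B = np.array([template_fiducials[k] for k in keys], float)
    else:
        A = np.asarray(measured_fiducials, float)
        B = np.asarray(template_fiducials, float)
    if A.shape != (3, 3) or B.shape != (3, 3):
        raise ValueError("exactly three 3-D point pairs are required")
    for P in (A, B):
        v1, v2 = P[1] - P[0], P[2] - P[0]
        cross = np.cross(v1, v2)
        if np.linalg.norm(cross) < 1e-9 * max(
            np.linalg.norm(v1) * np.linalg.norm(v2), 1.0
        ):
            raise DegenerateGeometryError("fiducials are collinear")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return RigidTransform(R, cb - R @ ca)


def apply_transform(t: RigidTransform, layout: ProbeLayout) -> ProbeLayout:
    """Map every optode and fiducial; channels and wavelengths unchanged."""
    return replace(
        layout,
        source_positions=t.apply(layout.source_positions),
        detector_positions=t.apply(layout.detector_positions),
        fiducials={k: t.apply(v) for k, v in layout.fiducials.items()},
    )


def project_optodes_to_surface(
    layout: ProbeLayout, head: HeadModel, max_snap_distance: float = 15.0
) -> ProbeLayout:
    """Snap each optode to the nearest head-surface voxel center.

    Surface voxels are inside voxels with at least one outside/out-of-grid
    face.  Raises :class:`CouplingError` naming the optode if the nearest
    surface voxel is farther than `max_snap_distance` mm.
    """
    surf = _surface_voxel_centers(head)

    def snap(points, kind):
        out = np.empty_like(points)
        for i, p in enumerate(points):
            d = np.linalg.norm(surf - p, axis=1)
            j = int(np.argmin(d))
            if d[j] > max_snap_distance:
                raise CouplingError(
                    f"{kind} {i} is {d[j]:.1f} mm from the scalp "
                    f"(max snap distance {max_snap_distance} mm)"
                )
            out[i] = surf[j]
        return out

    return replace(
        layout,
        source_positions=snap(layout.source_positions, "source"),
        detector_positions=snap(layout.detector_positions, "detector"),
    )


def fit_layout_to_head(layout: ProbeLayout, head: HeadModel) -> ProbeLayout:
    """Drape a planar (z=0) layout onto the head's upper surface.

    Each optode keeps its (x, y) and is lifted to the topmost inside voxel
    above the head-grid point nearest to (x + cx, y + cy), then snapped to
    the surface.  The layout is first translated so its centroid sits over
    the center of the head grid in x, y.
    """
    nx, ny, nz = head.grid_shape
    h = head.voxel_size
    cx, cy = nx * h / 2.0, ny * h / 2.0

    def lift(points):
        out = np.empty_like(points)
        for k, p in enumerate(points):
            x, y = p[0] + cx, p[1] + cy
            i, j, _ = head.position_to_index((x, y, 0.0))
            col = head.inside[i, j, :]
            if not col.any():
                raise CouplingError(f"no head tissue under optode at ({x:.0f},{y:.0f})")
            ktop = int(np.nonzero(col)[0][-1])
            out[k] = (x, y, (ktop + 0.5) * h)
        return out

    draped = replace(
        layout,
        source_positions=lift(layout.source_positions),
        detector_positions=lift(layout.detector_positions),
    )
    return project_optodes_to_surface(draped, head)


def _surface_voxel_centers(head: HeadModel) -> np.ndarray:
    inside = head.inside
    surf = np.zeros_like(inside)
    for axis in range(3):
        for shift in (1, -1):
            neighbor = np.roll(inside, shift, axis=axis)
            # rolled-in edge counts as outside (grid boundary face)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            neighbor[tuple(sl)] = False
            surf |= inside & ~neighbor
    idx = np.argwhere(surf)
    return (idx + 0.5) * head.voxel_size
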