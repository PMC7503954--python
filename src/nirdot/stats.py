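"""Single-subject voxel inference on chromophore time series.

Two procedures, chosen by task structure:

* block designs (SWG): a per-voxel GLM regressing the time course on the
  expected response (stimulation square wave convolved with the canonical
  HRF, band-limited identically to the data) plus intercept and linear
  drift; summarized by t = beta / SE(beta).
* unstructured tasks (DS backward, SS): standard deviations in
  non-overlapping 10 s windows are compared between the pre-task rest
  minute and the task with a Welch t statistic (task - rest).  The
  statistic sees only oscillation amplitude, never its sign.

Maps are thresholded at |t| > 1.65 (one-sided normal 0.05 critical value,
uncorrected) and restricted to the array-sensitivity mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import scipy.signal
import scipy.stats

from .forward import SensitivityMask
from .protocol import TaskDesign, design_vector
from .synth import canonical_hrf
from .tomo import HbMovie

__all__ = [
    "GlmFit",
    "VarianceComparison",
    "StatMap",
    "glm_tscores",
    "variance_tscores",
    "threshold_map",
    "anticorrelation_summary",
    "rounded_critical_value",
    "tmap_centroid",
]

DEFAULT_THRESHOLD = 1.65


class InsufficientDataError(ValueError):
    """Too few samples/windows/voxels for the requested statistic."""


@dataclass
class GlmFit:
    """Per-voxel GLM results for one chromophore."""

    beta: np.ndarray  # (n_voxels,)
    t_score: np.ndarray
    dof: float
    regressor: np.ndarray  # sampled expected response actually fitted
    zero_variance: np.ndarray  # voxels where t was forced to 0


@dataclass
class VarianceComparison:
    """Window-SD populations and their Welch t per voxel."""

    rest_sds: np.ndarray  # (n_voxels, n_rest_windows)
    task_sds: np.ndarray  # (n_voxels, n_task_windows)
    t_score: np.ndarray  # (n_voxels,)
    window_length: float


@dataclass
class StatMap:
    """Thresholded voxel t-map for one or both chromophores."""

    t_scores: dict  # chromophore -> full-grid volume
    suprathreshold: dict  # chromophore -> boolean full-grid volume
    mask: SensitivityMask
    threshold: float
    two_sided: bool
    method: str

    def to_nifti(self, chromophore: str, voxel_size: float):
        import nibabel as nib

        affine = np.diag([voxel_size] * 3 + [1.0])
        affine[:3, 3] = 0.5 * voxel_size
        return nib.Nifti1Image(
            self.t_scores[chromophore].astype(np.float32), affine
        )

    def suprathreshold_table(self, chromophore: str, voxel_size: float):
        """DataFrame of suprathreshold voxel coordinates (mm) and t-scores."""
        import pandas as pd

        idx = np.argwhere(self.suprathreshold[chromophore])
        pos = (idx + 0.5) * voxel_size
        t = self.t_scores[chromophore][tuple(idx.T)]
        return pd.DataFrame(
            {"x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2], "t": t}
        )


def rounded_critical_value(p: float = 0.05, ndigits: int = 2) -> float:
    """One-sided standard-normal critical value, table-rounded.

    Quantiles are conventionally quoted to 3 decimals (1.645 for p=0.05)
    and then half-up rounded when fewer digits are displayed, giving the
    1.65 threshold used for the maps.
    """
    z = scipy.stats.norm.ppf(1.0 - p)
    quoted = Decimal(f"{z:.3f}")
    return float(quoted.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def _band_filter_like(x: np.ndarray, fs: float, band: tuple, order: int = 4):
    """Apply the same zero-lag Butterworth band-pass the data received."""
    low, high = band
    sos = scipy.signal.butter(
        order, [low / (fs / 2), high / (fs / 2)], btype="bandpass", output="sos"
    )
    padlen = min(x.shape[-1] - 1, 3 * int(fs / (2 * low)))
    return scipy.signal.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def _fit_sample_mask(design: TaskDesign, n: int, fs: float) -> np.ndarray:
    """True for samples inside the task span (flanking rests excluded)."""
    t = np.arange(n) / fs
    keep = np.ones(n, bool)
    for onset, dur in design.event_table.epochs("rest"):
        keep[(t >= onset) & (t < onset + dur)] = False
    return keep


def glm_tscores(
    movie: HbMovie | np.ndarray,
    design: TaskDesign,
    hrf_params: dict | None = None,
    band: tuple | None = None,
    sampling_rate: float | None = None,
    exclude_rest: bool = True,
) -> GlmFit:
    """Per-voxel ordinary least squares on the expected response.

    The regressor is the stimulation indicator convolved with the
    canonical HRF; if `band` is given it is band-passed identically to the
    data.  Nuisance regressors: intercept and linear drift.  The flanking
    rest minutes are excluded from the fit by default.

    Degrees of freedom: ``n - p`` for unfiltered data; for band-limited
    data an effective dof ``n * 2 * high / fs`` (floored at 10, capped at
    ``n - p``) accounts for filtering-induced autocorrelation.

    Given an :class:`HbMovie`, returns ``{"o2hb": GlmFit, "hhb": GlmFit}``;
    given a (n_voxels, n_time) array, a single :class:`GlmFit`.
    """
    if isinstance(movie, HbMovie):
        return {
            chrom: glm_tscores(
                getattr(movie, chrom), design, hrf_params,
                band=band, sampling_rate=movie.sampling_rate,
                exclude_rest=exclude_rest,
            )
            for chrom in ("o2hb", "hhb")
        }
    data = np.atleast_2d(np.asarray(movie, float))
    if sampling_rate is None:
        raise ValueError("sampling_rate required for array input")
    fs = sampling_rate
    n = data.shape[1]

    stim = design_vector(design, n, fs)
    hrf = canonical_hrf(fs, **(hrf_params or {}))
    reg = np.convolve(stim, hrf)[:n]
    if reg.max() > 0:
        reg = reg / reg.max()
    if band is not None:
        reg = _band_filter_like(reg[None, :], fs, band)[0]

    keep = _fit_sample_mask(design, n, fs) if exclude_rest else np.ones(n, bool)
    nf = int(keep.sum())
    Y = data[:, keep].T  # (n_fit, n_vox)
    x = reg[keep]
    tt = np.linspace(-1.0, 1.0, nf)
    X = np.column_stack([x, np.ones(nf), tt])
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (constant regressor?)")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)  # (p, n_vox)
    resid = Y - X @ B
    if band is None:
        dof = float(nf - p)
    else:
        dof = float(np.clip(int(nf * 2.0 * band[1] / fs), 10, nf - p))
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 0.0))
    beta = B[0]
    zero = se <= 0
    t = np.zeros_like(beta)
    t[~zero] = beta[~zero] / se[~zero]
    return GlmFit(beta, t, dof, reg, zero)


def _window_sds(data: np.ndarray, start: float, stop: float, fs: float,
                window: float) -> np.ndarray:
    """SD of each voxel in non-overlapping windows of `window` s within
    [start, stop) seconds; returns (n_voxels, n_windows)."""
    wlen = int(round(window * fs))
    i0 = int(round(start * fs))
    i1 = int(round(stop * fs))
    n_win = (i1 - i0) // wlen
    sds = np.empty((data.shape[0], n_win))
    for k in range(n_win):
        seg = data[:, i0 + k * wlen : i0 + (k + 1) * wlen]
        sds[:, k] = seg.std(axis=1, ddof=1)
    return sds


def variance_tscores(
    movie: HbMovie | np.ndarray,
    design: TaskDesign,
    window: float = 10.0,
    sampling_rate: float | None = None,
) -> VarianceComparison:
    """Welch t on window-SD populations, task minus pre-task rest.

    Chromophore SDs are computed in non-overlapping `window`-second
    windows of the baseline (pre-task rest minute) and of the task
    epoch(s); the per-voxel statistic is a two-sample unequal-variance t
    of task vs rest SDs.  Positive t means increased oscillation amplitude
    during the task.  Sign-blind: flipping the series' sign leaves the
    statistic unchanged exactly.

    Given an :class:`HbMovie`, returns a dict over both chromophores.
    """
    if isinstance(movie, HbMovie):
        return {
            chrom: variance_tscores(
                getattr(movie, chrom), design, window,
                sampling_rate=movie.sampling_rate,
            )
            for chrom in ("o2hb", "hhb")
        }
    data = np.atleast_2d(np.asarray(movie, float))
    if sampling_rate is None:
        raise ValueError("sampling_rate required for array input")
    fs = sampling_rate

    b0, b1 = design.baseline_window
    rest_sds = _window_sds(data, b0, b1, fs, window)
    task_parts = [
        _window_sds(data, onset, onset + dur, fs, window)
        for onset, dur in design.stimulation_epochs()
    ]
    task_sds = np.concatenate(task_parts, axis=1) if task_parts else np.empty((data.shape[0], 0))
    if rest_sds.shape[1] < 2 or task_sds.shape[1] < 2:
        raise InsufficientDataError(
            f"need >= 2 windows on each side, got {rest_sds.shape[1]} rest / "
            f"{task_sds.shape[1]} task"
        )
    t, _ = scipy.stats.ttest_ind(task_sds, rest_sds, axis=1, equal_var=False)
    return VarianceComparison(rest_sds, task_sds, np.nan_to_num(t), window)


def threshold_map(
    t_scores: dict,
    mask: SensitivityMask,
    geometry,
    threshold: float = DEFAULT_THRESHOLD,
    two_sided: bool = True,
    method: str = "GLM",
) -> StatMap:
    """Label suprathreshold voxels inside the sensitivity mask.

    `t_scores` maps chromophore name to a flat (n_inside,) array;
    `geometry` is any object with `flat_indices` and `grid_shape`
    (an :class:`HbMovie` or :class:`Jacobian`).  GLM maps are two-sided
    (|t| > threshold); variance maps one-sided (t > threshold).
    """
    volumes, supra = {}, {}
    for chrom, t_flat in t_scores.items():
        t_flat = np.asarray(t_flat, float)
        if not np.all(np.isfinite(t_flat[mask.mask.ravel()[geometry.flat_indices]])):
            raise ValueError("non-finite t-scores inside the mask")
        full = np.zeros(int(np.prod(geometry.grid_shape)))
        full[geometry.flat_indices] = t_flat
        full = full.reshape(geometry.grid_shape)
        full[~mask.mask] = 0.0
        exceed = np.abs(full) > threshold if two_sided else full > threshold
        supra[chrom] = exceed & mask.mask
        volumes[chrom] = full
    return StatMap(volumes, supra, mask, float(threshold), two_sided, method)


def anticorrelation_summary(
    t_o2hb: np.ndarray, t_hhb: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation of the two chromophore t-maps over masked voxels.

    A strongly negative value is the signature of a neurovascular response
    (opposed O2Hb/HHb oscillations); reported as a scalar diagnostic.
    """
    a = np.asarray(t_o2hb)[np.asarray(mask, bool)]
    b = np.asarray(t_hhb)[np.asarray(mask, bool)]
    if a.size < 3:
        raise InsufficientDataError("fewer than 3 masked voxels")
    return float(np.corrcoef(a, b)[0, 1])


def tmap_centroid(
    t_flat: np.ndarray, movie: HbMovie, power: float = 2.0
) -> np.ndarray:
    """Positive-t weighted centroid (mm) of a flat t-map inside the mask."""
    mask_flat = movie.mask.mask.ravel()[movie.flat_indices]
    w = np.clip(np.asarray(t_flat, float), 0.0, None) ** power
    w[~mask_flat] = 0.0
    if w.sum() == 0:
        raise InsufficientDataError("no positive t-scores inside the mask")
    return (movie.voxel_positions() * w[:, None]).sum(axis=0) / w.sum()
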