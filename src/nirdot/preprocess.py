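"""Channel-level preprocessing of dual-wavelength DC intensities.

The chain mirrors standard CW-fNIRS practice: mean-normalization and
conversion to optical density, motion-artifact correction, zero-lag 4th
order Butterworth band-pass (0.01-0.3 Hz), and a modified Beer-Lambert
conversion to channel hemoglobin for signal-quality inspection.  All
stages operate on arrays shaped (wavelength, channel, time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .constants import (
    DEFAULT_DPF,
    DEFAULT_SAMPLING_RATE,
    extinction_matrix,
)
from .probe import ProbeLayout
from .protocol import EventTable, TaskDesign

__all__ = [
    "OpticalRecording",
    "ODSeries",
    "ChannelHb",
    "to_optical_density",
    "motion_correct",
    "bandpass",
    "mbll_channels",
    "block_average",
    "channel_quality",
]


class DataQualityError(ValueError):
    """Physically impossible sample values (e.g. non-positive intensity)."""


@dataclass
class OpticalRecording:
    """Raw DC intensities: (wavelength, channel, time), strictly positive."""

    intensities: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    layout: ProbeLayout | None = None
    events: EventTable | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (wavelength, channel, time)")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class ODSeries:
    """Optical density (wavelength, channel, time) with provenance flags."""

    od: np.ndarray
    sampling_rate: float
    layout: ProbeLayout | None = None
    events: EventTable | None = None
    normalized: bool = True
    motion_corrected: bool = False
    filtered: bool = False
    band: tuple | None = None
    bad_channels: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    def decimated(self, factor: int) -> "ODSeries":
        """Keep every `factor`-th sample (call after band-pass filtering,
        which already removed content above the new Nyquist)."""
        if not self.filtered:
            raise ValueError("decimate only after band-pass filtering")
        return replace(
            self,
            od=np.ascontiguousarray(self.od[..., ::factor]),
            sampling_rate=self.sampling_rate / factor,
        )


@dataclass
class ChannelHb:
    """Channel-space hemoglobin concentration changes (uM)."""

    o2hb: np.ndarray  # (channel, time)
    hhb: np.ndarray
    sampling_rate: float
    dpf: dict = field(default_factory=lambda: dict(DEFAULT_DPF))
    extinction: np.ndarray = field(default_factory=extinction_matrix)


def to_optical_density(rec: OpticalRecording) -> ODSeries:
    """Mean-normalize and convert to OD: ``od = -ln(I / mean_t(I))``.

    Raises :class:`DataQualityError` naming the first offending channel and
    sample if any intensity is non-positive.
    """
    I = rec.intensities
    if np.any(I <= 0):
        w, c, t = np.argwhere(I <= 0)[0]
        raise DataQualityError(
            f"non-positive intensity at wavelength index {w}, channel {c}, sample {t}"
        )
    od = -np.log(I / I.mean(axis=-1, keepdims=True))
    return ODSeries(
        od, rec.sampling_rate, layout=rec.layout, events=rec.events
    )


def motion_correct(
    od: ODSeries,
    spike_z: float = 8.0,
    dilate_s: float = 0.5,
    level_window_s: float = 2.0,
    shift_z: float = 6.0,
    max_bad_fraction: float = 0.5,
) -> ODSeries:
    """Detect and repair motion artifacts in OD time series.

    Samples whose first difference exceeds ``spike_z`` robust standard
    deviations (MAD-based) are flagged, dilated by ``dilate_s`` seconds and
    merged into artifact spans.  Each span is replaced by a cubic-spline
    bridge fitted to the clean samples flanking it; if the post-span
    baseline remains shifted by more than ``shift_z`` robust SDs (a step
    artifact), the tail of the series is re-leveled and the shift logged.
    Channels with more than ``max_bad_fraction`` flagged samples are marked
    bad and excluded downstream.  Unflagged samples outside any logged
    artifact's influence region are returned unchanged.
    """
    if od.filtered:
        raise ValueError("motion correction must precede band-pass filtering")
    out = od.od.copy()
    fs = od.sampling_rate
    dilate = max(1, int(round(dilate_s * fs)))
    lvl_w = max(2, int(round(level_window_s * fs)))
    artifacts: list = []
    bad = set(od.bad_channels)

    for w in range(out.shape[0]):
        for c in range(out.shape[1]):
            x = out[w, c]
            dx = np.diff(x)
            sigma_d = 1.4826 * np.median(np.abs(dx - np.median(dx)))
            if sigma_d == 0:
                continue
            hits = np.flatnonzero(np.abs(dx) > spike_z * sigma_d)
            if hits.size == 0:
                continue
            flagged = np.zeros(x.size, bool)
            for i in hits:
                flagged[max(0, i - dilate) : min(x.size, i + 1 + dilate)] = True
            if flagged.mean() > max_bad_fraction:
                bad.add(c)
                artifacts.append(
                    {"wavelength": w, "channel": c, "kind": "bad_channel",
                     "fraction_flagged": float(flagged.mean())}
                )
                continue
            for a, b in _spans(flagged):
                _bridge(x, a, b, lvl_w)
                pre = x[max(0, a - lvl_w) : a]
                post = x[b : b + lvl_w]
                rec = {"wavelength": w, "channel": c, "kind": "spike",
                       "start": int(a), "end": int(b)}
                if pre.size >= 2 and post.size >= 2:
                    offset = float(np.median(post) - np.median(pre))
                    sigma_loc = 1.4826 * np.median(
                        np.abs(pre - np.median(pre))
                    ) + 1e-15
                    if abs(offset) > shift_z * sigma_loc:
                        x[a:] -= offset
                        rec["kind"] = "shift"
                        rec["offset"] = offset
                        rec["end"] = int(x.size)
                artifacts.append(rec)
    return replace(
        od,
        od=out,
        motion_corrected=True,
        artifacts=od.artifacts + artifacts,
        bad_channels=sorted(bad),
    )


def _spans(flagged: np.ndarray):
    edges = np.diff(flagged.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if flagged[0]:
        starts.insert(0, 0)
    if flagged[-1]:
        ends.append(flagged.size)
    return zip(starts, ends)


def _bridge(x: np.ndarray, a: int, b: int, anchor_w: int) -> None:
    """Replace x[a:b] by a cubic-spline bridge over flanking clean samples."""
    from scipy.interpolate import CubicSpline

    left = np.arange(max(0, a - anchor_w), a)
    right = np.arange(b, min(x.size, b + anchor_w))
    anchors = np.concatenate([left, right])
    if left.size < 2 or right.size < 2:
        fill = np.median(x[anchors]) if anchors.size else 0.0
        x[a:b] = fill
        return
    cs = CubicSpline(anchors, x[anchors])
    x[a:b] = cs(np.arange(a, b))


def bandpass(
    od: ODSeries, low: float = 0.01, high: float = 0.3, order: int = 4
) -> ODSeries:
    """Zero-lag Butterworth band-pass (two-pass ``filtfilt``).

    The filter is applied forward and backward so the net phase response
    is zero; the stated `order` is the order of each pass.  Odd-reflection
    padding of three settling lengths (one settling length = half a period
    of the low cutoff) suppresses edge transients.
    """
    fs = od.sampling_rate
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq:.3f} Hz)")
    settling = int(fs / (2.0 * low))
    n = od.n_samples
    if n < 3 * settling:
        raise ValueError(
            f"series of {n} samples is shorter than 3x the filter settling "
            f"length ({settling} samples) for low cutoff {low} Hz"
        )
    sos = scipy.signal.butter(order, [low / nyq, high / nyq], btype="bandpass",
                              output="sos")
    padlen = min(n - 1, 3 * settling)
    filt = scipy.signal.sosfiltfilt(sos, od.od, axis=-1, padtype="odd",
                                    padlen=padlen)
    return replace(od, od=filt, filtered=True, band=(low, high))


def mbll_channels(
    od: ODSeries,
    layout: ProbeLayout | None = None,
    dpf: dict | None = None,
    extinction: np.ndarray | None = None,
) -> ChannelHb:
    """Channel-space modified Beer-Lambert inversion.

    Per channel and sample solves the 2x2 system
    ``dOD(lambda) = [eps_O2Hb dC_O2Hb + eps_HHb dC_HHb] * d * DPF(lambda)``
    with d the source-detector distance, giving concentration changes in uM.
    """
    layout = layout or od.layout
    if layout is None:
        raise ValueError("a probe layout is required for MBLL")
    dpf = dict(DEFAULT_DPF) if dpf is None else dpf
    wl = layout.wavelengths
    E = extinction_matrix(wl) if extinction is None else np.asarray(extinction)
    dists = layout.sd_distances()
    if np.any(dists <= 0):
        raise ValueError("zero source-detector distance in layout")
    dpf_vec = np.array([dpf[w] for w in wl])
    n_ch, n_t = od.od.shape[1], od.od.shape[2]
    o2hb = np.empty((n_ch, n_t))
    hhb = np.empty((n_ch, n_t))
    for c in range(n_ch):
        M = E * (dists[c] * dpf_vec)[:, None]  # (wavelength, chromophore)
        sol = np.linalg.solve(M, od.od[:, c, :])
        o2hb[c], hhb[c] = sol[0], sol[1]
    return ChannelHb(o2hb, hhb, od.sampling_rate, dpf=dpf, extinction=E)


@dataclass
class BlockAverage:
    """Stimulation-locked average epoch response per channel."""

    times: np.ndarray  # s relative to stimulation onset
    o2hb: np.ndarray  # (channel, time)
    hhb: np.ndarray
    n_epochs: int


def block_average(
    hb: ChannelHb,
    design: TaskDesign,
    pre_s: float = 10.0,
    post_s: float = 20.0,
) -> BlockAverage:
    """Average the response over stimulation epochs, time-locked to onset.

    Each epoch spans [-pre_s, duration + post_s] around its onset; the
    mean of the pre-onset interval is subtracted per epoch (baseline).
    Epochs extending past the recording end are truncated with a warning.
    """
    import warnings

    epochs = design.stimulation_epochs()
    if not epochs:
        raise ValueError("design has no stimulation epochs")
    fs = hb.sampling_rate
    dur = max(d for _, d in epochs)
    i_pre = int(round(pre_s * fs))
    i_len = i_pre + int(round((dur + post_s) * fs))
    n_t = hb.o2hb.shape[1]
    acc_o, acc_h, count = 0.0, 0.0, 0
    for onset, _ in epochs:
        i0 = int(round(onset * fs)) - i_pre
        if i0 < 0:
            continue
        if i0 + i_len > n_t:
            warnings.warn("epoch extends past recording end; truncating")
            continue
        seg_o = hb.o2hb[:, i0 : i0 + i_len]
        seg_h = hb.hhb[:, i0 : i0 + i_len]
        base_o = seg_o[:, :i_pre].mean(axis=1, keepdims=True) if i_pre else 0.0
        base_h = seg_h[:, :i_pre].mean(axis=1, keepdims=True) if i_pre else 0.0
        acc_o = acc_o + (seg_o - base_o)
        acc_h = acc_h + (seg_h - base_h)
        count += 1
    if count == 0:
        raise ValueError("no complete epochs within the recording")
    times = (np.arange(i_len) - i_pre) / fs
    return BlockAverage(times, acc_o / count, acc_h / count, count)


def channel_quality(rec: OpticalRecording, cv_threshold: float = 0.5) -> np.ndarray:
    """Boolean good-channel mask from the coefficient of variation of raw
    intensity (pluggable quality predicate; default is deliberately loose)."""
    I = rec.intensities
    cv = I.std(axis=-1) / I.mean(axis=-1)
    return (cv < cv_threshold).all(axis=0)
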