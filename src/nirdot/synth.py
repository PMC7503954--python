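"""Synthetic dual-wavelength CW recordings with known ground truth.

The generator places a spherical hemodynamic activation in gray matter
(O2Hb increase with a 2-3x smaller HHb decrease, the canonical
neurovascular response), adds physiological oscillations (cardiac,
respiratory, Mayer waves), slow drift, extracranial (scalp-layer)
interference and measurement noise, maps voxel concentration changes to
channel optical density through the forward-model Jacobian (Rytov), and
exponentiates to DC intensities.  Motion artifacts are injected in the OD
domain.  Everything is seeded and bit-reproducible.

Voxel time series are represented as a low-rank sum of (spatial weight
vector) x (time course) components, which keeps simulation cheap and gives
tests an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import EXTINCTION, TISSUE_GRAY, TISSUE_SCALP_SKULL, DEFAULT_SAMPLING_RATE
from .forward import Jacobian
from .headmodel import HeadModel
from .preprocess import OpticalRecording
from .probe import ProbeLayout
from .protocol import TaskDesign, design_vector

__all__ = [
    "ActivationSpec",
    "NoiseSpec",
    "SyntheticRecording",
    "canonical_hrf",
    "simulate_recording",
    "inject_motion",
]


def canonical_hrf(
    sampling_rate: float,
    peak_time: float = 6.0,
    undershoot_time: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Peak-normalized double-gamma hemodynamic response kernel.

    Positive lobe peaking at `peak_time` s followed by an undershoot with
    mode at `undershoot_time` s and relative amplitude `undershoot_ratio`;
    the kernel spans `length` s and its maximum is exactly 1.
    """
    from scipy.stats import gamma

    if min(sampling_rate, peak_time, undershoot_time, undershoot_ratio, length) <= 0:
        raise ValueError("all HRF parameters must be positive")
    t = np.arange(0.0, length, 1.0 / sampling_rate)
    # shape = mode + 1 with unit scale puts each gamma's mode at the stated time
    h = gamma.pdf(t, peak_time + 1.0) - undershoot_ratio * gamma.pdf(
        t, undershoot_time + 1.0
    )
    return h / h.max()


@dataclass
class ActivationSpec:
    """Spherical activation in gray matter.

    `peak_o2hb` is the peak voxel O2Hb increase (uM); the HHb trough is
    ``-peak_o2hb / hhb_ratio`` (default ratio 2.5, within the 2-3x band of
    a neurovascular response).
    """

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 10.0
    peak_o2hb: float = 1.0
    hhb_ratio: float = 2.5
    hrf: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("activation radius must be positive")
        if self.hhb_ratio <= 0:
            raise ValueError("hhb_ratio must be positive")


@dataclass
class NoiseSpec:
    """Amplitudes of the simulated nuisance processes.

    Oscillation amplitudes are voxel-level concentration modulations (uM)
    in gray matter; `ect_gain` scales the same family of oscillations in
    the scalp layer (extracranial interference).  `measurement` is the
    multiplicative intensity noise fraction.  `motion` is (spike rate per
    minute, spike amplitude in OD, probability a motion event is a baseline
    step rather than a spike).
    """

    cardiac: tuple = (1.1, 0.6)
    respiratory: tuple = (0.25, 0.35)
    mayer: tuple = (0.1, 0.3)
    drift: float = 0.04  # uM per sqrt(s), random walk
    measurement: float = 0.003
    ect_gain: float = 1.0
    motion: tuple = (0.5, 0.2, 0.3)

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls((1.1, 0.0), (0.25, 0.0), (0.1, 0.0), 0.0, 0.0, 0.0, (0.0, 0.0, 0.0))


@dataclass
class SyntheticRecording:
    """A simulated recording plus its exact ground truth."""

    recording: OpticalRecording
    design: TaskDesign
    truth: dict
    seed: int
    geometry_hash: str


def simulate_recording(
    head: HeadModel,
    layout: ProbeLayout,
    design: TaskDesign,
    activation: ActivationSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    jacobian: Jacobian | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> SyntheticRecording:
    """Generate a dual-wavelength DC intensity recording with ground truth.

    See module docstring for the generative model.  `jacobian` may be
    passed in to reuse forward solutions across seeds (it is validated
    against the head model's geometry hash).
    """
    from .forward import compute_jacobian

    ghash = head.geometry_hash()
    if jacobian is None:
        jacobian = compute_jacobian(head, layout)
    elif jacobian.geometry_hash != ghash:
        raise ValueError("jacobian geometry hash does not match the head model")
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(seed)

    n = int(round(design.total_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    flat = jacobian.flat_indices
    labels = head.tissue_label.ravel()[flat]
    centers = (
        np.array(np.unravel_index(flat, head.grid_shape)).T + 0.5
    ) * head.voxel_size

    components = []  # (weights over inside voxels, o2hb(t), hhb(t))
    truth: dict = {"seed": seed}

    if activation is not None:
        center = np.asarray(activation.center, float)
        ci = head.position_to_index(center)
        if head.tissue_label[ci] != TISSUE_GRAY:
            raise ValueError(
                f"activation center {center} is not in gray matter "
                f"(tissue {int(head.tissue_label[ci])})"
            )
        in_sphere = np.linalg.norm(centers - center, axis=1) <= activation.radius
        w_act = (in_sphere & (labels == TISSUE_GRAY)).astype(float)
        stim = design_vector(design, n, sampling_rate)
        hrf = canonical_hrf(sampling_rate, **activation.hrf)
        resp = np.convolve(stim, hrf)[:n]
        if resp.max() > 0:
            resp = resp / resp.max()
        o2 = activation.peak_o2hb * resp
        hh = -o2 / activation.hhb_ratio
        components.append((w_act, o2, hh))
        truth["activation"] = {
            "spec": activation,
            "voxel_weights": w_act,
            "o2hb": o2,
            "hhb": hh,
            "center": center,
        }

    gray = (labels == TISSUE_GRAY).astype(float)
    scalp = (labels == TISSUE_SCALP_SKULL).astype(float)
    dt = 1.0 / sampling_rate

    def oscillations(scale: float) -> tuple[np.ndarray, np.ndarray]:
        o2 = np.zeros(n)
        hh = np.zeros(n)
        for f, a in (noise.cardiac, noise.respiratory, noise.mayer):
            o2 += scale * a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            hh += scale * a * 0.3 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        if noise.drift > 0:
            o2 += np.cumsum(rng.normal(0.0, noise.drift * np.sqrt(dt), n))
            hh += np.cumsum(rng.normal(0.0, 0.5 * noise.drift * np.sqrt(dt), n))
        return o2, hh

    phys_o2, phys_hh = oscillations(1.0)
    components.append((gray, phys_o2, phys_hh))
    if noise.ect_gain > 0:
        ect_o2, ect_hh = oscillations(noise.ect_gain)
        components.append((scalp, ect_o2, ect_hh))
    truth["components"] = components

    wavelengths = [float(w) for w in layout.wavelengths]
    n_ch = layout.n_channels
    od = np.zeros((len(wavelengths), n_ch, n))
    for iw, w in enumerate(wavelengths):
        J = jacobian.matrices[w]
        eps_o = EXTINCTION[("o2hb", w)]
        eps_h = EXTINCTION[("hhb", w)]
        for weights, o2, hh in components:
            gain = J @ weights  # per-channel path integral of the pattern
            od[iw] += np.outer(gain, eps_o * o2 + eps_h * hh)

    motion_events: list = []
    rate, amp, shift_prob = noise.motion
    if rate > 0 and amp > 0:
        od, motion_events = inject_motion(
            od, rate_per_min=rate, amplitude=amp, shift_probability=shift_prob,
            sampling_rate=sampling_rate, rng=rng,
        )
    truth["motion_events"] = motion_events

    I0 = np.stack([jacobian.amplitudes[w] for w in wavelengths])  # (wl, ch)
    I = I0[:, :, None] * np.exp(-od)
    if noise.measurement > 0:
        factor = 1.0 + noise.measurement * rng.standard_normal(I.shape)
        I = I * np.clip(factor, 1e-3, None)

    rec = OpticalRecording(I, sampling_rate, layout=layout, events=design.event_table)
    return SyntheticRecording(rec, design, truth, seed, ghash)


def inject_motion(
    od_series: np.ndarray,
    rate_per_min: float,
    amplitude: float,
    shift_probability: float = 0.3,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, list]:
    """Add motion artifacts to an OD array (wavelength, channel, time).

    Events arrive as a Poisson process at `rate_per_min` per recording
    minute;
    each event hits one channel, identically at both wavelengths, and is
    either a decaying-exponential spike (< 2 s, time constant 0.3 s) or,
    with `shift_probability`, a persistent baseline step of half the spike
    amplitude.  Returns the modified array and the injected-event list
    (ground truth for motion-correction tests).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    od = od_series.copy()
    n_wl, n_ch, n = od.shape
    minutes = n / sampling_rate / 60.0
    events: list = []
    if rate_per_min <= 0 or amplitude <= 0:
        return od, events
    n_events = rng.poisson(rate_per_min * minutes)
    tau = 0.3 * sampling_rate
    span = int(min(2.0 * sampling_rate, n))
    for _ in range(n_events):
        ch = int(rng.integers(n_ch))
        i0 = int(rng.integers(n))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if rng.random() < shift_probability:
            od[:, ch, i0:] += sign * 0.5 * amplitude
            events.append({"kind": "shift", "channel": ch, "sample": i0,
                           "amplitude": sign * 0.5 * amplitude})
        else:
            k = np.arange(min(span, n - i0))
            od[:, ch, i0 : i0 + k.size] += sign * amplitude * np.exp(-k / tau)
            events.append({"kind": "spike", "channel": ch, "sample": i0,
                           "amplitude": sign * amplitude})
    return od, events
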