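"""Minimal SNIRF (HDF5) container I/O for CW intensity recordings.

Implements the subset of the SNIRF v1.0 layout the pipeline needs: one
`/nirs` block with `data1` (dataTimeSeries + measurementList), `probe`
(wavelengths, 3-D optode positions, landmarks) and `stim` groups.  Round
trips are lossless at stored (float64) precision.
"""

from __future__ import annotations

import numpy as np

from .preprocess import OpticalRecording
from .probe import ProbeLayout
from .protocol import EventTable

__all__ = ["write_snirf", "read_snirf", "SnirfFormatError"]


class SnirfFormatError(ValueError):
    """File does not contain the required SNIRF groups/fields."""


def write_snirf(rec: OpticalRecording, path) -> None:
    """Write a recording (intensities + probe + events) as a SNIRF file.

    Measurement columns are ordered wavelength-major: column
    ``iw * n_channels + ch`` holds channel `ch` at wavelength index `iw`.
    """
    import h5py

    layout = rec.layout
    if layout is None:
        raise ValueError("recording has no probe layout to store")
    n_wl, n_ch, n_t = rec.intensities.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        cols = rec.intensities.reshape(n_wl * n_ch, n_t).T  # (time, measurement)
        data.create_dataset("dataTimeSeries", data=cols)
        data.create_dataset("time", data=rec.times)
        m = 1
        for iw in range(n_wl):
            for s, d in layout.channels:
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=np.int32(s + 1))
                ml.create_dataset("detectorIndex", data=np.int32(d + 1))
                ml.create_dataset("wavelengthIndex", data=np.int32(iw + 1))
                ml.create_dataset("dataType", data=np.int32(1))  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=np.int32(1))
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(layout.wavelengths, float))
        probe.create_dataset("sourcePos3D", data=layout.source_positions)
        probe.create_dataset("detectorPos3D", data=layout.detector_positions)
        if layout.fiducials:
            names = sorted(layout.fiducials)
            probe.create_dataset(
                "landmarkPos3D",
                data=np.array([layout.fiducials[k] for k in names], float),
            )
            probe.create_dataset(
                "landmarkLabels",
                data=np.array(names, dtype=h5py.string_dtype()),
            )
        if rec.events is not None:
            labels = sorted({l for l, _, _ in rec.events.events})
            for i, label in enumerate(labels, start=1):
                g = nirs.create_group(f"stim{i}")
                g.create_dataset("name", data=label)
                rows = [
                    (o, d, 1.0) for l, o, d in rec.events.events if l == label
                ]
                g.create_dataset("data", data=np.asarray(rows, float))


def read_snirf(path) -> OpticalRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible).

    Raises :class:`SnirfFormatError` listing missing groups, or if the
    measurement list does not cover both probe wavelengths.
    """
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f.get("nirs") or f.get("nirs1")
        if nirs is None:
            raise SnirfFormatError("missing required group: /nirs")
        missing = [g for g in ("data1", "probe") if g not in nirs]
        if missing:
            raise SnirfFormatError(f"missing required group(s): {missing}")
        probe = nirs["probe"]
        for fld in ("wavelengths", "sourcePos3D", "detectorPos3D"):
            if fld not in probe:
                raise SnirfFormatError(f"probe is missing field {fld!r}")
        wavelengths = tuple(float(w) for w in probe["wavelengths"][()])
        data = nirs["data1"]
        ts = data["dataTimeSeries"][()]
        time = data["time"][()]
        if time.size < 2:
            raise SnirfFormatError("time axis has fewer than 2 samples")
        fs = 1.0 / float(np.mean(np.diff(time)))

        mls = sorted(
            (k for k in data if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not mls:
            raise SnirfFormatError("data1 has no measurementList entries")
        entries = [
            (
                int(data[k]["sourceIndex"][()]) - 1,
                int(data[k]["detectorIndex"][()]) - 1,
                int(data[k]["wavelengthIndex"][()]) - 1,
            )
            for k in mls
        ]
        wl_seen = {iw for _, _, iw in entries}
        if wl_seen != set(range(len(wavelengths))):
            missing_wl = [wavelengths[i] for i in set(range(len(wavelengths))) - wl_seen]
            raise SnirfFormatError(f"no measurements at wavelength(s) {missing_wl}")

        channels = []
        for s, d, iw in entries:
            if iw == 0:
                channels.append((s, d))
        n_ch = len(channels)
        n_wl = len(wavelengths)
        if len(entries) != n_ch * n_wl:
            raise SnirfFormatError("measurement list is not wavelength-complete")

        fiducials = {}
        if "landmarkPos3D" in probe and "landmarkLabels" in probe:
            pos = probe["landmarkPos3D"][()]
            labs = [
                l.decode() if isinstance(l, bytes) else str(l)
                for l in probe["landmarkLabels"][()]
            ]
            fiducials = {l: np.asarray(p, float) for l, p in zip(labs, pos)}
        layout = ProbeLayout(
            probe["sourcePos3D"][()],
            probe["detectorPos3D"][()],
            fiducials,
            channels,
            wavelengths,
        )

        intensities = np.empty((n_wl, n_ch, ts.shape[0]))
        for col, (s, d, iw) in enumerate(entries):
            ch = channels.index((s, d))
            intensities[iw, ch] = ts[:, col]

        events = None
        stim_keys = sorted(k for k in nirs if k.startswith("stim"))
        if stim_keys:
            evs = []
            for k in stim_keys:
                g = nirs[k]
                name = g["name"][()]
                name = name.decode() if isinstance(name, bytes) else str(name)
                for row in np.atleast_2d(g["data"][()]):
                    evs.append((name, float(row[0]), float(row[1])))
            total = max(time[-1] + 1.0 / fs, max(o + d for _, o, d in evs))
            events = EventTable(evs, total, fs)

    return OpticalRecording(intensities, fs, layout=layout, events=events)
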