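import warnings

import numpy as np
import pytest

from nirdot.constants import DEFAULT_DPF, extinction_matrix
from nirdot.preprocess import (
    ChannelHb,
    DataQualityError,
    ODSeries,
    OpticalRecording,
    bandpass,
    block_average,
    mbll_channels,
    motion_correct,
    to_optical_density,
)
from nirdot.probe import ProbeLayout
from nirdot.protocol import build_swg

FS = 39.7365


def _od(arr, fs=FS, **kw):
    return ODSeries(np.asarray(arr, float), fs, **kw)


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        rec = OpticalRecording(np.full((2, 3, 100), 7.5), FS)
        assert np.allclose(to_optical_density(rec).od, 0.0, atol=1e-14)

    def test_single_sample_dip_closed_form(self):
        n = 1000
        I = np.full((1, 1, n), 2.0)
        I[0, 0, 500] = 2.0 * np.exp(-0.1)
        od = to_optical_density(OpticalRecording(I, FS)).od[0, 0]
        mean = I[0, 0].mean()
        assert np.isclose(od[500], 0.1 - np.log(2.0 / mean))
        assert np.isclose(od[0], -np.log(2.0 / mean))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        I = np.exp(rng.normal(0, 0.01, (2, 4, 500))) * 3.0
        a = to_optical_density(OpticalRecording(I, FS)).od
        b = to_optical_density(OpticalRecording(I * 123.4, FS)).od
        assert np.allclose(a, b, atol=1e-12)

    def test_nonpositive_intensity_named(self):
        I = np.ones((2, 3, 50))
        I[1, 2, 17] = 0.0
        with pytest.raises(DataQualityError, match="channel 2, sample 17"):
            to_optical_density(OpticalRecording(I, FS))


class TestMotionCorrect:
    def _clean(self, n=12000, n_ch=4, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / FS
        base = 2e-3 * np.sin(2 * np.pi * 0.1 * t) + 1e-3 * np.sin(
            2 * np.pi * 1.1 * t
        )
        od = base + rng.normal(0, 2e-4, (2, n_ch, n))
        return od

    def test_clean_data_mostly_untouched(self):
        clean = self._clean()
        out = motion_correct(_od(clean))
        altered = np.mean(out.od != clean)
        assert altered <= 0.01
        assert out.bad_channels == []

    def test_unflagged_samples_unchanged_exactly(self):
        clean = self._clean()
        dirty = clean.copy()
        t0 = 6000
        k = np.arange(60)
        dirty[:, 1, t0 : t0 + 60] += 0.5 * np.exp(-k / (0.3 * FS))
        out = motion_correct(_od(dirty))
        touched = np.zeros(dirty.shape[-1], bool)
        for ev in out.artifacts:
            if ev["channel"] == 1 and "start" in ev:
                touched[ev["start"] : ev["end"]] = True
        assert touched.any()
        assert np.array_equal(out.od[:, 1, ~touched], dirty[:, 1, ~touched])
        # untouched channels bit-identical
        assert np.array_equal(out.od[:, 0], dirty[:, 0])

    def test_spike_suppressed_five_fold(self):
        clean = self._clean()
        dirty = clean.copy()
        k = np.arange(60)
        dirty[:, 2, 4000:4060] += 0.5 * np.exp(-k / (0.3 * FS))
        out = motion_correct(_od(dirty))
        before = np.abs(dirty[0, 2] - clean[0, 2]).max()
        after = np.abs(out.od[0, 2] - clean[0, 2]).max()
        assert after <= before / 5.0

    def test_step_shift_releveled(self):
        clean = self._clean()
        dirty = clean.copy()
        dirty[:, 0, 5000:] += 0.3
        out = motion_correct(_od(dirty))
        resid = np.abs(out.od[0, 0] - clean[0, 0])
        assert np.median(resid[6000:]) < 0.01

    def test_zero_series_unchanged(self):
        z = np.zeros((2, 2, 1000))
        out = motion_correct(_od(z))
        assert np.array_equal(out.od, z)


class TestBandpass:
    def _sine(self, f, n=int(300 * FS)):
        t = np.arange(n) / FS
        return np.sin(2 * np.pi * f * t)

    def test_cardiac_attenuated_hundredfold(self):
        x = self._sine(1.1)
        y = bandpass(_od(x[None, None, :])).od[0, 0]
        # projection onto the 1.1 Hz tone isolates the cardiac component
        # from low-frequency edge leakage
        n = x.size
        t = np.arange(n) / FS
        mid = slice(2000, n - 2000)
        amp = np.hypot(
            2 * np.mean(y[mid] * np.sin(2 * np.pi * 1.1 * t[mid])),
            2 * np.mean(y[mid] * np.cos(2 * np.pi * 1.1 * t[mid])),
        )
        assert amp < 1.0 / 100.0

    def test_passband_amplitude_and_phase_preserved(self):
        f = 0.05
        n = int(600 * FS)
        x = self._sine(f, n)
        y = bandpass(_od(x[None, None, :])).od[0, 0]
        t = np.arange(n) / FS
        mid = slice(int(100 * FS), int(500 * FS))
        c = np.cos(2 * np.pi * f * t[mid])
        s = np.sin(2 * np.pi * f * t[mid])
        a_s = 2 * np.mean(y[mid] * s)
        a_c = 2 * np.mean(y[mid] * c)
        amp = np.hypot(a_s, a_c)
        phase_deg = np.degrees(np.arctan2(a_c, a_s))
        assert abs(amp - 1.0) < 0.05
        assert abs(phase_deg) < 1.0

    def test_impulse_response_is_symmetric(self):
        n = int(300 * FS)
        x = np.zeros(n)
        x[n // 2] = 1.0
        y = bandpass(_od(x[None, None, :])).od[0, 0]
        w = 2000
        seg = y[n // 2 - w : n // 2 + w + 1]
        assert np.allclose(seg, seg[::-1], atol=1e-6 * np.abs(seg).max())

    def test_idempotent_in_passband(self):
        x = self._sine(0.05, int(600 * FS))
        y1 = bandpass(_od(x[None, None, :]))
        y2 = bandpass(ODSeries(y1.od, FS))
        mid = slice(int(100 * FS), int(500 * FS))
        a1 = y1.od[0, 0, mid].std()
        a2 = y2.od[0, 0, mid].std()
        assert abs(a2 / a1 - 1.0) < 0.05

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="settling"):
            bandpass(_od(np.zeros((1, 1, 100))))

    def test_band_must_be_below_nyquist(self):
        with pytest.raises(ValueError):
            bandpass(_od(np.zeros((1, 1, 10000)), fs=0.5))


class TestMbll:
    def _layout(self, n_ch=3, dist=30.0):
        srcs = [[0.0, 0.0, 0.0]]
        dets = [[dist, 15.0 * i, 0.0] for i in range(n_ch)]
        return ProbeLayout(srcs, dets, {}, [(0, i) for i in range(n_ch)])

    def test_zero_od_gives_zero_concentration(self):
        hb = mbll_channels(_od(np.zeros((2, 3, 50))), self._layout())
        assert not hb.o2hb.any() and not hb.hhb.any()

    def test_roundtrip_known_concentrations(self):
        layout = self._layout(n_ch=2)
        E = extinction_matrix()
        d = layout.sd_distances()
        dpf = np.array([DEFAULT_DPF[690.0], DEFAULT_DPF[830.0]])
        conc = np.array([1.0, -0.4])  # uM
        n = 20
        od = np.empty((2, 2, n))
        for c in range(2):
            dod = (E @ conc) * d[c] * dpf
            od[:, c, :] = dod[:, None]
        hb = mbll_channels(_od(od), layout)
        assert np.allclose(hb.o2hb, 1.0, atol=1e-10)
        assert np.allclose(hb.hhb, -0.4, atol=1e-10)

    def test_zero_distance_rejected(self):
        layout = ProbeLayout([[0.0, 0, 0]], [[0.0, 0, 0]], {}, [(0, 0)])
        with pytest.raises(ValueError, match="distance"):
            mbll_channels(_od(np.zeros((2, 1, 10))), layout)


class TestBlockAverage:
    # 40 Hz makes every epoch an integer number of samples, so the
    # "identical epochs" identity is exact
    BA_FS = 40.0

    def _hb(self, signal, n_ch=2):
        return ChannelHb(
            np.tile(signal, (n_ch, 1)), -0.4 * np.tile(signal, (n_ch, 1)),
            self.BA_FS,
        )

    def test_identical_epochs_average_to_one_epoch(self):
        design = build_swg()
        fs = self.BA_FS
        n = int(round(design.total_duration * fs))
        t = np.arange(n) / fs
        sig = np.zeros(n)
        for onset, dur in design.stimulation_epochs():
            sel = (t >= onset) & (t < onset + dur)
            sig[sel] = np.sin(np.linspace(0, np.pi, sel.sum()))
        ba = block_average(self._hb(sig), design)
        i0 = int(round(60.0 * fs)) - int(round(10.0 * fs))
        single = sig[i0 : i0 + len(ba.times)]
        assert ba.n_epochs == 5
        assert np.allclose(ba.o2hb[0], single, atol=1e-12)

    def test_averaging_reduces_noise_sqrt_n(self):
        design = build_swg()
        n = int(round(design.total_duration * self.BA_FS))
        sds = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            ba = block_average(self._hb(rng.normal(0, 1.0, n), n_ch=1), design)
            sds.append(ba.o2hb[0].std())
        mean_sd = np.mean(sds)
        assert abs(mean_sd - 1.0 / np.sqrt(5)) < 0.15

    def test_truncated_epoch_warns(self):
        design = build_swg(rest=5.0)  # trailing epoch runs into the end
        n = int(round((design.total_duration - 20.0) * self.BA_FS))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            block_average(self._hb(np.zeros(n)), design)
        assert any("truncat" in str(w.message) for w in rec)
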