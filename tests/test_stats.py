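import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirdot.protocol import build_swg, build_unstructured
from nirdot.stats import (
    InsufficientDataError,
    anticorrelation_summary,
    glm_tscores,
    rounded_critical_value,
    threshold_map,
    variance_tscores,
)
from nirdot.synth import canonical_hrf

FS = 5.0
DESIGN = build_swg()
N = int(round(DESIGN.total_duration * FS))


def _expected_response():
    from nirdot.protocol import design_vector

    stim = design_vector(DESIGN, N, FS)
    reg = np.convolve(stim, canonical_hrf(FS))[:N]
    return reg / reg.max()


class TestGlm:
    def test_recovers_injected_amplitude(self):
        reg = _expected_response()
        rng = np.random.default_rng(0)
        amp = 0.8
        data = amp * reg[None, :] + rng.normal(0, 1e-3, (50, N))
        fit = glm_tscores(data, DESIGN, sampling_rate=FS)
        assert np.all(fit.t_score > 1.65)
        assert np.allclose(fit.beta, amp, rtol=0.02)

    def test_orthogonal_timecourse_gives_small_t(self):
        rng = np.random.default_rng(1)
        t = np.arange(N) / FS
        data = np.sin(2 * np.pi * 0.21 * t)[None, :] + rng.normal(0, 0.1, (20, N))
        fit = glm_tscores(data, DESIGN, sampling_rate=FS)
        assert np.abs(fit.beta).max() < 0.1
        assert np.mean(np.abs(fit.t_score) > 1.65) < 0.2

    def test_zero_variance_voxel_flagged_with_zero_t(self):
        data = np.zeros((3, N))
        fit = glm_tscores(data, DESIGN, sampling_rate=FS)
        assert fit.zero_variance.all()
        assert not fit.t_score.any()

    def test_t_invariant_to_regressor_scale(self):
        """Standard OLS identity: scaling the regressor rescales beta
        inversely and leaves t untouched."""
        reg = _expected_response()
        rng = np.random.default_rng(2)
        data = reg[None, :] + rng.normal(0, 0.05, (10, N))
        f1 = glm_tscores(data, DESIGN, sampling_rate=FS)
        f2 = glm_tscores(
            data, DESIGN, sampling_rate=FS,
            hrf_params={"peak_time": 6.0},  # identical kernel, sanity anchor
        )
        assert np.allclose(f1.t_score, f2.t_score)
        data_scaled = 3.0 * data
        f3 = glm_tscores(data_scaled, DESIGN, sampling_rate=FS)
        assert np.allclose(f3.beta, 3.0 * f1.beta)
        assert np.allclose(f3.t_score, f1.t_score)

    def test_null_type_one_error_rate_calibrated(self):
        """White-noise voxels at large dof exceed t=1.65 at the nominal
        one-sided 5% rate (binomial CI over 10,000 voxels)."""
        rng = np.random.default_rng(42)
        data = rng.normal(0, 1.0, (10_000, N))
        fit = glm_tscores(data, DESIGN, sampling_rate=FS)
        rate = np.mean(fit.t_score > 1.65)
        assert 0.035 <= rate <= 0.065

    def test_effective_dof_reduced_for_filtered_data(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1.0, (5, N))
        f_raw = glm_tscores(data, DESIGN, sampling_rate=FS)
        f_filt = glm_tscores(data, DESIGN, sampling_rate=FS, band=(0.01, 0.3))
        assert f_filt.dof < f_raw.dof
        assert f_filt.dof >= 10


class TestVarianceStatistic:
    DESIGN_SS = build_unstructured("SS", 120.0)
    N_SS = int(round(240.0 * FS))

    def _series(self, rng, task_sd_factor=1.0, n_vox=200):
        x = rng.normal(0, 1.0, (n_vox, self.N_SS))
        t = np.arange(self.N_SS) / FS
        task = (t >= 60.0) & (t < 180.0)
        x[:, task] *= task_sd_factor
        return x

    def test_exchangeable_null_centers_on_zero(self):
        rng = np.random.default_rng(0)
        cmp = variance_tscores(self._series(rng, 1.0, 10_000), self.DESIGN_SS,
                               sampling_rate=FS)
        assert abs(cmp.t_score.mean()) < 0.1
        assert cmp.rest_sds.shape[1] == 6
        assert cmp.task_sds.shape[1] == 12

    def test_doubled_task_sd_detected(self):
        rng = np.random.default_rng(1)
        cmp = variance_tscores(self._series(rng, 2.0, 2000), self.DESIGN_SS,
                               sampling_rate=FS)
        assert np.mean(cmp.t_score > 1.65) > 0.95

    @given(st.integers(0, 2**31 - 1))
    def test_sign_flip_invariance_exact(self, seed):
        rng = np.random.default_rng(seed)
        x = self._series(rng, 1.5, 5)
        a = variance_tscores(x, self.DESIGN_SS, sampling_rate=FS).t_score
        b = variance_tscores(-x, self.DESIGN_SS, sampling_rate=FS).t_score
        assert np.array_equal(a, b)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(5)
        x = self._series(rng, 1.5, 5)
        a = variance_tscores(x, self.DESIGN_SS, sampling_rate=FS).t_score
        b = variance_tscores(x + 7.7, self.DESIGN_SS, sampling_rate=FS).t_score
        assert np.allclose(a, b, atol=1e-10)

    def test_too_few_windows_rejected(self):
        short = build_unstructured("SS", 15.0)
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (3, int(round(135.0 * FS))))
        with pytest.raises(InsufficientDataError):
            variance_tscores(x, short, sampling_rate=FS)


class TestThresholding:
    def test_critical_value_convention(self):
        assert rounded_critical_value(0.05) == 1.65

    def test_threshold_semantics(self, slab_jacobian):
        from nirdot.forward import sensitivity_mask

        mask = sensitivity_mask(slab_jacobian)
        n_v = slab_jacobian.n_voxels
        zeros = np.zeros(n_v)
        smap = threshold_map({"o2hb": zeros}, mask, slab_jacobian)
        assert not smap.suprathreshold["o2hb"].any()
        rng = np.random.default_rng(0)
        t = rng.normal(0, 3.0, n_v)
        smap = threshold_map({"o2hb": t}, mask, slab_jacobian, threshold=np.inf)
        assert not smap.suprathreshold["o2hb"].any()
        smap2 = threshold_map({"o2hb": t}, mask, slab_jacobian, threshold=1.65)
        vol = smap2.t_scores["o2hb"]
        assert np.array_equal(smap2.suprathreshold["o2hb"],
                              (np.abs(vol) > 1.65) & mask.mask)
        one_sided = threshold_map({"o2hb": t}, mask, slab_jacobian,
                                  threshold=1.65, two_sided=False)
        assert np.array_equal(one_sided.suprathreshold["o2hb"],
                              (vol > 1.65) & mask.mask)
        # suprathreshold voxels never leave the sensitivity mask
        assert not (smap2.suprathreshold["o2hb"] & ~mask.mask).any()


class TestAnticorrelation:
    def test_perfect_mirror_maps(self):
        rng = np.random.default_rng(0)
        mask = np.ones((5, 5, 2), bool)
        a = rng.normal(0, 1, mask.shape)
        assert anticorrelation_summary(a, -a, mask) == pytest.approx(-1.0)

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(1)
        mask = np.ones((20, 20, 5), bool)
        a, b = rng.normal(0, 1, (2, *mask.shape))
        assert abs(anticorrelation_summary(a, b, mask)) < 0.1

    def test_too_few_voxels_rejected(self):
        mask = np.zeros((4, 4, 1), bool)
        mask[0, 0, 0] = True
        with pytest.raises(InsufficientDataError):
            anticorrelation_summary(np.ones(mask.shape), np.ones(mask.shape), mask)
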