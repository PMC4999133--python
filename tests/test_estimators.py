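import numpy as np
import pytest

from scdmri import estimators as est
from scdmri import phantom as ph
from scdmri.dwi_io import DWIStudy
from scdmri.estimators import (fit_tensor, tensor_metrics, tensor_to_matrix,
                               fit_adc_per_direction, two_direction_metrics,
                               angular_deviation, frame_projected_metrics,
                               RankDeficientSchemeError)
from scdmri.schemes import (GradientScheme, AcquisitionProtocol,
                            builtin_protocol, design_matrix)

from conftest import make_flat_study


def char_poly_eigvals(D):
    """Independent 3x3 symmetric eigensolver via the characteristic
    polynomial (trigonometric closed form), descending order."""
    D = np.asarray(D, dtype=float)
    q = np.trace(D) / 3.0
    B = D - q * np.eye(3)
    p = np.sqrt(np.trace(B @ B) / 6.0)
    if p < 1e-30:
        return np.full(3, q)
    detB = np.linalg.det(B / p)
    phi = np.arccos(np.clip(detB / 2.0, -1.0, 1.0)) / 3.0
    lams = q + 2 * p * np.cos(phi + np.array([0, -2, 2]) * np.pi / 3.0)
    return np.sort(lams)[::-1]


@pytest.fixture
def diag_study(protocol_b):
    return make_flat_study(protocol_b, [1.5, 0.3, 0.3, 0, 0, 0],
                           s0=1000.0, n_voxels=4, sigma=0.0, seed=0)


class TestFitTensor:
    def test_noiseless_exact_recovery(self, diag_study):
        f = fit_tensor(diag_study, method="ols")
        np.testing.assert_allclose(f.tensor[0, 0, 0],
                                   [1.5, 0.3, 0.3, 0, 0, 0], atol=1e-10)

    def test_s0_recovery(self, diag_study):
        f = fit_tensor(diag_study)
        assert f.s0[0, 0, 0] == pytest.approx(1000.0, rel=1e-8)

    def test_wls_noiseless_exact(self, diag_study):
        f = fit_tensor(diag_study, method="wls")
        np.testing.assert_allclose(f.tensor[0, 0, 0],
                                   [1.5, 0.3, 0.3, 0, 0, 0], atol=1e-10)

    def test_ols_matches_pseudoinverse_oracle(self, protocol_b):
        rng = np.random.default_rng(3)
        study = make_flat_study(protocol_b, [1.4, 0.4, 0.35, 0.05, 0.02, 0.01],
                                s0=500.0, n_voxels=50, sigma=10.0, seed=2)
        f = fit_tensor(study, method="ols")
        X = design_matrix(study.scheme)
        y = np.log(study.data.reshape(-1, study.scheme.n_volumes)).T
        beta = np.linalg.pinv(X) @ y          # brute-force oracle
        np.testing.assert_allclose(f.tensor.reshape(-1, 6), beta[:6].T,
                                   atol=1e-10)

    def test_rank_deficient_scheme_directs_to_two_dir(self, protocol_c,
                                                      wt_subject):
        study = ph.simulate_study(wt_subject, protocol_c, 0.0, 0)
        with pytest.raises(RankDeficientSchemeError,
                           match="two_direction"):
            fit_tensor(study)

    def test_zero_signal_floored_and_flagged(self, protocol_b):
        study = make_flat_study(protocol_b, [1.5, 0.3, 0.3, 0, 0, 0],
                                s0=100.0, n_voxels=2, sigma=0.0, seed=0)
        data = study.data.copy()
        data[0, 0, 0, -1] = 0.0
        study2 = DWIStudy(data=data, voxel_size=study.voxel_size,
                          scheme=study.scheme)
        f = fit_tensor(study2)
        assert f.flags[0, 0, 0] & est.FLAG_FLOORED
        assert not f.flags[1, 0, 0] & est.FLAG_FLOORED


class TestTensorMetrics:
    def test_isotropic(self):
        tm = tensor_metrics(np.array([0.7, 0.7, 0.7, 0, 0, 0]))
        assert tm.fa == pytest.approx(0.0, abs=1e-12)
        assert tm.md == pytest.approx(0.7)
        assert tm.ad == pytest.approx(0.7)
        assert tm.rd == pytest.approx(0.7)
        assert tm.flags & est.FLAG_DEGENERATE_V1

    def test_prolate_frozen_value(self):
        tm = tensor_metrics(np.array([1.5, 0.3, 0.3, 0, 0, 0]))
        # closed form: sqrt(3/2)*sqrt(0.64+2*0.16)/sqrt(2.25+2*0.09)
        expected = np.sqrt(1.5) * np.sqrt(0.96) / np.sqrt(2.43)
        assert expected == pytest.approx(0.769800, abs=1e-6)
        assert tm.fa == pytest.approx(expected, rel=1e-12)
        assert tm.md == pytest.approx(0.7)
        assert tm.ad == pytest.approx(1.5)
        assert tm.rd == pytest.approx(0.3)

    def test_rank_one_limit(self):
        tm = tensor_metrics(np.array([1.0, 0.0, 0.0, 0, 0, 0]))
        assert tm.fa == pytest.approx(1.0, rel=1e-12)

    def test_matches_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            A = rng.normal(size=(3, 3))
            D = (A + A.T) / 2.0
            t6 = np.array([D[0, 0], D[1, 1], D[2, 2],
                           D[0, 1], D[0, 2], D[1, 2]])
            tm = tensor_metrics(t6)
            np.testing.assert_allclose(tm.evals, char_poly_eigvals(D),
                                       atol=1e-10)

    def test_v1_sign_convention(self):
        # principal axis along -z must be flipped to +z
        D = 0.3 * np.eye(3) + 1.2 * np.outer([0, 0, -1], [0, 0, -1])
        t6 = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
        tm = tensor_metrics(t6)
        assert tm.v1[2] > 0

    def test_negative_eigenvalue_flagged_not_clamped(self):
        tm = tensor_metrics(np.array([1.0, 0.5, -0.2, 0, 0, 0]))
        assert tm.flags & est.FLAG_NEG_EIGENVALUE
        assert tm.evals[2] == pytest.approx(-0.2)
        assert tm.md == pytest.approx((1.0 + 0.5 - 0.2) / 3)
        assert 0.0 <= tm.fa <= 1.0


class TestAdcPerDirection:
    def _study_c(self, adc_s=0.5, adc_r=0.5, s0=1000.0):
        protocol = builtin_protocol("C")
        return make_flat_study(protocol,
                               [adc_r, adc_r, adc_s, 0, 0, 0],
                               s0=s0, n_voxels=2, sigma=0.0, seed=0)

    def test_exact_recovery(self):
        study = self._study_c(adc_s=0.5)
        adc = fit_adc_per_direction(study, "slice")
        np.testing.assert_allclose(adc, 0.5, atol=1e-12)

    def test_read_direction(self):
        study = self._study_c(adc_s=1.5, adc_r=0.3)
        np.testing.assert_allclose(fit_adc_per_direction(study, "read"),
                                   0.3, atol=1e-12)

    def test_flat_signals_give_zero(self, protocol_c):
        data = np.full((2, 1, 1, protocol_c.scheme.n_volumes), 500.0)
        study = DWIStudy(data=data, voxel_size=(1, 1, 1),
                         scheme=protocol_c.scheme)
        np.testing.assert_allclose(fit_adc_per_direction(study, "slice"),
                                   0.0, atol=1e-12)

    def test_direction_absent_from_scheme(self, protocol_b):
        study = make_flat_study(protocol_b, [1.0, 1.0, 1.0, 0, 0, 0],
                                s0=100.0, n_voxels=1, sigma=0.0, seed=0)
        with pytest.raises(ValueError, match="slice"):
            fit_adc_per_direction(study, "slice")

    def test_biexp_adc_below_b0_tangent(self, protocol_c):
        # bi-exponential decay: fitted ADC < the b->0 tangent diffusivity
        f, d_fast, d_slow = 0.7, 1.5, 0.5
        b = protocol_c.scheme.full_bvalues()
        g = protocol_c.scheme.full_directions()
        along = np.abs(g @ np.array([0, 0, 1.0])) > 0.99
        sig = 1000.0 * (f * np.exp(-b * d_fast) + (1 - f) * np.exp(-b * d_slow))
        sig[~along & (b > 0)] = 1000.0 * np.exp(-b[~along & (b > 0)] * 0.3)
        data = np.tile(sig, (2, 1, 1, 1))
        study = DWIStudy(data=data, voxel_size=(1, 1, 1),
                         scheme=protocol_c.scheme)
        adc = fit_adc_per_direction(study, "slice")[0, 0, 0]
        # oracle: numeric derivative of ln S at b = 0
        eps = 1e-6
        s_at = lambda bb: f * np.exp(-bb * d_fast) + (1 - f) * np.exp(-bb * d_slow)
        tangent = -(np.log(s_at(eps)) - np.log(s_at(0.0))) / eps
        assert tangent == pytest.approx(f * d_fast + (1 - f) * d_slow,
                                        rel=1e-4)
        assert adc < tangent


class TestTwoDirectionMetrics:
    def test_isotropy(self):
        td = two_direction_metrics(0.7, 0.7)
        assert td.md == pytest.approx(0.7)
        assert td.fa == pytest.approx(0.0, abs=1e-15)

    def test_matches_tensor_formula(self):
        td = two_direction_metrics(1.5, 0.3)
        tm = tensor_metrics(np.array([0.3, 0.3, 1.5, 0, 0, 0]))
        assert td.md == pytest.approx(0.7, rel=1e-15)
        assert float(td.fa) == pytest.approx(float(tm.fa), rel=1e-12)
        assert float(td.ad) == pytest.approx(float(tm.ad))
        assert float(td.rd) == pytest.approx(float(tm.rd))

    def test_edge_case_zero_slice_adc(self):
        td = two_direction_metrics(0.0, 1.0)
        assert td.md == pytest.approx(2.0 / 3.0, rel=1e-15)

    def test_double_zero_convention(self):
        td = two_direction_metrics(0.0, 0.0)
        assert td.fa == 0.0

    def test_negative_input_flagged(self):
        td = two_direction_metrics(-0.1, 0.5)
        assert td.flags & est.FLAG_NEG_INPUT


class TestAngularDeviation:
    def test_aligned(self):
        assert angular_deviation(np.array([0, 0, 1.0])) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert angular_deviation(np.array([1.0, 0, 0])) == pytest.approx(90.0)

    def test_thirty_degrees(self):
        v = np.array([0.0, 0.5, np.sqrt(3) / 2])
        assert angular_deviation(v) == pytest.approx(30.0, abs=1e-9)

    def test_sign_ambiguity(self):
        v = np.array([0.0, 0.5, -np.sqrt(3) / 2])
        assert angular_deviation(v) == pytest.approx(30.0, abs=1e-9)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            angular_deviation(np.array([0, 0, 1.0]), slice_axis=[0, 0, 0])

    def test_nan_propagates(self):
        out = angular_deviation(np.array([[np.nan] * 3, [0, 0, 1.0]]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.0)


class TestFrameProjection:
    def test_diagonal_tensor_no_deviation(self):
        out = frame_projected_metrics(np.array([0.3, 0.4, 1.5, 0, 0, 0]))
        for name in ("AD", "RD", "MD", "FA"):
            assert out["relative_deviation"][name] == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_md_trace_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            A = rng.normal(size=(3, 3))
            D = (A + A.T) / 2
            t6 = np.array([D[0, 0], D[1, 1], D[2, 2],
                           D[0, 1], D[0, 2], D[1, 2]])
            out = frame_projected_metrics(t6)
            tm = tensor_metrics(t6)
            assert abs(out["MD"] - tm.md) <= 1e-14

    def test_tilted_axisymmetric_tensor(self):
        # oracle: brute-force rotation of diag(1.5, 0.3, 0.3)
        t = np.deg2rad(10.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(t), -np.sin(t)],
                      [0, np.sin(t), np.cos(t)]])
        D = R @ np.diag([0.3, 0.3, 1.5]) @ R.T
        t6 = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
        out = frame_projected_metrics(t6)
        assert out["AD"] < 1.5
        assert out["RD"] > 0.3
        assert out["AD"] == pytest.approx(
            1.5 * np.cos(t) ** 2 + 0.3 * np.sin(t) ** 2, rel=1e-12)

    def test_read_only_radial_variant(self):
        t6 = np.array([0.2, 0.6, 1.5, 0, 0, 0])
        both = frame_projected_metrics(t6, radial="both")
        read = frame_projected_metrics(t6, radial="read")
        assert both["RD"] == pytest.approx(0.4)
        assert read["RD"] == pytest.approx(0.2)

    def test_non_orthonormal_axes_rejected(self):
        with pytest.raises(ValueError):
            frame_projected_metrics(np.array([1, 1, 1, 0, 0, 0.0]),
                                    axes=np.ones((3, 3)))


class TestRoundTripProperties:
    def test_noiseless_pipeline_roundtrip_b(self, small_spec, protocol_b):
        subj = ph.make_subject(small_spec, "WT01", seed=0)
        study = ph.simulate_study(subj, protocol_b, 0.0, 0)
        rois = subj.rois()
        tm = tensor_metrics(fit_tensor(study, mask=rois.cord_mask()))
        for roi in ("vWM", "dlWM", "vGM"):
            gt = subj.params[roi].metrics()
            m = rois.mask(roi)
            np.testing.assert_allclose(tm.fa[m], gt["FA"], rtol=1e-8)
            np.testing.assert_allclose(tm.md[m], gt["MD"], rtol=1e-8)

    def test_axisymmetric_alignment_identity(self, small_spec, protocol_c):
        subj = ph.make_subject(small_spec, "WT01", seed=0)
        study = ph.simulate_study(subj, protocol_c, 0.0, 0)
        rois = subj.rois()
        mask = rois.cord_mask()
        td = two_direction_metrics(
            fit_adc_per_direction(study, "slice", mask=mask),
            fit_adc_per_direction(study, "read", mask=mask))
        m = rois.mask("vWM")   # axis aligned with slice direction
        gt = subj.params["vWM"].metrics()
        np.testing.assert_allclose(td.fa[m], gt["FA"], rtol=1e-10)
        np.testing.assert_allclose(td.md[m], gt["MD"], rtol=1e-10)
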