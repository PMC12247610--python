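"""Preprocessing: censoring, outlier detection, nuisance and evoked regression."""

import numpy as np
import pytest

from lamconn.contrast import CONTROL, NULLED, PairedSeries, VolumeSeries, pair_series
from lamconn.preprocess import (
    CensorMask,
    MotionTrace,
    censor,
    legendre_basis,
    outlier_fraction,
    regress_evoked,
    regress_nuisance,
)


def _paired(n_pairs, n_vox=1):
    shape = (n_vox, 1, 1, n_pairs)
    return PairedSeries(
        vaper=np.ones(shape),
        bold=np.ones(shape),
        effective_tr=2.0,
        control_indices=np.arange(n_pairs) * 2 + 1,
        nulled_indices=np.arange(n_pairs) * 2,
        pair_times=np.arange(n_pairs, dtype=float),
        affine=np.eye(4),
    )


def _motion_from_deriv(deriv_rows):
    """Motion params whose backward differences equal the given rows."""
    d = np.asarray(deriv_rows, dtype=float)
    return MotionTrace(np.cumsum(d, axis=0))


class TestEnormCensoring:
    def test_small_step_kept(self):
        d = np.zeros((4, 6))
        d[1] = [0.3, 0, 0, 0, 0, 0]
        motion = _motion_from_deriv(d)
        assert motion.enorm[1] == pytest.approx(0.3)
        mask = censor(motion, _paired(2))
        assert mask.keep.all()

    def test_combined_step_censored(self):
        d = np.zeros((4, 6))
        d[1] = [0.3, 0.3, 0, 0, 0, 0]
        motion = _motion_from_deriv(d)
        assert motion.enorm[1] == pytest.approx(np.sqrt(0.18))  # ~0.424
        mask = censor(motion, _paired(2))
        assert not mask.keep[0] and "motion" in mask.reasons[0]
        assert mask.keep[1]

    def test_outlier_exactly_at_threshold_censored(self):
        motion = MotionTrace(np.zeros((4, 6)))
        ofrac = np.array([0.0, 0.10, 0.0, 0.0])  # "at least 10%" is inclusive
        mask = censor(motion, _paired(2), volume_outlier_frac=ofrac)
        assert not mask.keep[0] and "outlier" in mask.reasons[0]

    def test_dummy_censored(self):
        motion = MotionTrace(np.zeros((4, 6)))
        mask = censor(
            motion, _paired(2), dummy_volumes=np.array([True, False, False, False])
        )
        assert not mask.keep[0] and "dummy" in mask.reasons[0]

    def test_all_censored_is_error(self):
        motion = MotionTrace(np.zeros((4, 6)))
        with pytest.raises(ValueError, match="no usable data"):
            censor(motion, _paired(2), dummy_volumes=np.ones(4, dtype=bool))

    def test_first_volume_derivative_zero(self):
        motion = MotionTrace(np.full((3, 6), 5.0))
        assert motion.derivative[0].tolist() == [0.0] * 6


class TestOutlierFraction:
    def test_constant_series(self):
        data = np.full((4, 4, 1, 20), 7.0)
        frac = outlier_fraction(data, np.ones((4, 4, 1), bool))
        np.testing.assert_array_equal(frac, 0.0)

    def test_pure_polynomial_absorbed(self):
        t = np.linspace(-1, 1, 30)
        trend = 1 + t + t**2 + t**3 + t**4 + t**5
        data = np.tile(trend, (5, 2, 1, 1))
        frac = outlier_fraction(data, np.ones((5, 2, 1), bool))
        np.testing.assert_array_equal(frac, 0.0)

    def test_displaced_voxels_detected(self, rng):
        n_vox, T = 100, 40
        data = rng.standard_normal((n_vox, 1, 1, T))
        mad = np.median(
            np.abs(data - np.median(data, axis=-1, keepdims=True)), axis=-1
        )
        data[:20, 0, 0, 7] += 10 * mad[:20, 0, 0]  # 20% of voxels at volume 7
        frac = outlier_fraction(data, np.ones((n_vox, 1, 1), bool))
        assert frac[7] == pytest.approx(0.2, abs=0.05)

    def test_exclude_keeps_trend_honest(self):
        # a scaled leading dummy must not distort the trend fit
        T = 22
        data = np.full((3, 1, 1, T), 100.0)
        data[..., :2] *= 1.05
        exclude = np.zeros(T, bool)
        exclude[:2] = True
        frac = outlier_fraction(data, np.ones((3, 1, 1), bool), exclude=exclude)
        np.testing.assert_array_equal(frac[2:], 0.0)

    def test_too_few_timepoints(self):
        data = np.zeros((2, 1, 1, 4))
        with pytest.raises(ValueError):
            outlier_fraction(data, np.ones((2, 1, 1), bool))


def _nuisance_setup(rng, T=40, nx=6):
    """A small grid with GM / WM / CSF slabs and zero motion."""
    shape = (nx, 3, 3)
    gm = np.zeros(shape, bool)
    wm = np.zeros(shape, bool)
    csf = np.zeros(shape, bool)
    gm[: nx // 3] = True
    wm[nx // 3 : 2 * nx // 3] = True
    csf[2 * nx // 3 :] = True
    vaper = np.empty(shape + (T,))
    vaper[...] = 1.0
    paired = PairedSeries(
        vaper=vaper,
        bold=np.ones(shape + (T,)),
        effective_tr=2.0,
        control_indices=np.arange(T) * 2 + 1,
        nulled_indices=np.arange(T) * 2,
        pair_times=np.arange(T, dtype=float),
        affine=np.eye(4),
    )
    motion = MotionTrace(0.001 * rng.standard_normal((2 * T, 6)))
    keep = np.ones(T, bool)
    cens = CensorMask(keep=keep, reasons=[set() for _ in range(T)])
    return paired, motion, gm, wm, csf, cens


class TestRegressNuisance:
    def test_motion_regressor_removed(self, rng):
        paired, motion, gm, wm, csf, cens = _nuisance_setup(rng)
        T = paired.n_pairs
        m_pair = 0.5 * (
            motion.params[paired.nulled_indices] + motion.params[paired.control_indices]
        )
        sig = 5.0 + m_pair[:, 0]
        paired.vaper[gm] = sig  # series equal to a motion regressor + constant
        paired.vaper[wm] = 1.0 + 0.01 * rng.standard_normal((wm.sum(), T))
        paired.vaper[csf] = 1.0 + 0.01 * rng.standard_normal((csf.sum(), T))
        resid = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        rel = np.linalg.norm(resid[gm]) / np.linalg.norm(sig)
        assert rel < 1e-8

    def test_orthogonal_series_passes_through(self, rng):
        paired, motion, gm, wm, csf, cens = _nuisance_setup(rng)
        motion = MotionTrace(np.zeros_like(motion.params))
        T = paired.n_pairs
        # construct a series exactly orthogonal to the effective design
        # (zero motion and constant CSF/WM reduce it to the Legendre basis)
        X = legendre_basis(T, 5)
        sig = rng.standard_normal(T)
        sig -= X @ np.linalg.lstsq(X, sig, rcond=None)[0]
        mu = 10.0
        paired.vaper[gm] = mu + sig
        paired.vaper[wm] = 1.0
        paired.vaper[csf] = 1.0
        with pytest.warns(UserWarning, match="rank-deficient"):
            resid = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        # residuals equal the demeaned series divided by the voxel mean
        expect = sig / np.mean(mu + sig)
        np.testing.assert_allclose(resid[gm][0], expect, atol=1e-10)

    def test_planted_csf_coupling_removed(self, rng):
        paired, motion, gm, wm, csf, cens = _nuisance_setup(rng)
        T = paired.n_pairs
        csf_sig = rng.standard_normal(T)
        cs = csf_sig - csf_sig.mean()
        # an extra signal exactly orthogonal to the design span so the CSF
        # coupling estimate is not contaminated
        X = np.column_stack([legendre_basis(T, 5), cs])
        indep = rng.standard_normal(T)
        indep -= X @ np.linalg.lstsq(X, indep, rcond=None)[0]
        paired.vaper[csf] = 50.0 + csf_sig
        paired.vaper[wm] = 1.0
        gm_series = 10.0 + 0.2 * cs + indep  # planted coupling 0.2
        paired.vaper[gm] = gm_series
        resid = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        r = np.corrcoef(resid[gm][0], csf_sig)[0, 1]
        assert abs(r) < 1e-6
        # recovered CSF coupling: project the removed part back on the CSF signal
        removed = gm_series / np.mean(gm_series) - resid[gm][0]
        beta = (removed - removed.mean()) @ cs / (cs @ cs)
        assert beta == pytest.approx(0.2 / np.mean(gm_series), rel=1e-6)

    def test_residual_orthogonality_to_design(self, rng):
        paired, motion, gm, wm, csf, cens = _nuisance_setup(rng)
        T = paired.n_pairs
        paired.vaper[gm] = 5.0 + rng.standard_normal((gm.sum(), T))
        paired.vaper[wm] = 2.0 + rng.standard_normal((wm.sum(), T))
        paired.vaper[csf] = 3.0 + rng.standard_normal((csf.sum(), T))
        resid = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        R = resid[gm]
        m_pair = 0.5 * (
            motion.params[paired.nulled_indices] + motion.params[paired.control_indices]
        )
        deriv = np.zeros_like(m_pair)
        deriv[1:] = np.diff(m_pair, axis=0)
        csf_mean = paired.vaper[csf].mean(axis=0)
        X = np.column_stack([legendre_basis(T, 5), m_pair, deriv, csf_mean])
        X /= np.linalg.norm(X, axis=0)
        for j in range(R.shape[0]):
            r = R[j]
            rn = r / np.linalg.norm(r)
            assert np.max(np.abs(rn @ X)) < 1e-8

    def test_scale_invariance(self, rng):
        paired, motion, gm, wm, csf, cens = _nuisance_setup(rng)
        T = paired.n_pairs
        base = 5.0 + rng.standard_normal((gm.sum(), T))
        paired.vaper[gm] = base
        paired.vaper[wm] = 2.0
        paired.vaper[csf] = 3.0
        r1 = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        paired.vaper *= 2.0  # doubling raw signal leaves residuals unchanged
        r2 = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        np.testing.assert_allclose(r1[gm], r2[gm], atol=1e-10)

    def test_censored_pairs_are_nan(self, rng):
        paired, motion, gm, wm, csf, cens = _nuisance_setup(rng)
        cens.keep[3] = False
        paired.vaper[gm] = 5.0 + rng.standard_normal((gm.sum(), paired.n_pairs))
        resid = regress_nuisance(paired, motion, csf, wm, cens, gm_mask=gm)
        assert np.isnan(resid[gm][:, 3]).all()
        assert np.isfinite(resid[gm][:, 4]).all()


class TestRegressEvoked:
    def test_exact_removal_inside_mask(self):
        T = 20
        ev = np.sin(np.arange(T))
        vals = np.zeros((4, 3, T))
        vals[:2] = 2.0 + 3.0 * ev
        vals[2:] = 2.0 + 3.0 * ev
        mask = np.array([True, True, False, False])
        out = regress_evoked(vals, ev, mask)
        assert np.max(np.abs(out[:2])) < 1e-10
        np.testing.assert_array_equal(out[2:], vals[2:])  # unchanged outside

    def test_zero_variance_regressor_noop(self):
        vals = np.random.default_rng(1).standard_normal((2, 2, 10))
        with pytest.warns(UserWarning, match="zero variance"):
            out = regress_evoked(vals, np.ones(10), np.array([True, True]))
        np.testing.assert_array_equal(out, vals)

    def test_empty_mask_identity(self):
        vals = np.random.default_rng(1).standard_normal((2, 2, 10))
        out = regress_evoked(vals, np.arange(10.0), np.array([False, False]))
        np.testing.assert_array_equal(out, vals)

    def test_shared_response_masks_latent_difference(self, rng):
        # two groups with independent latents plus a strong shared evoked
        # response: regression reveals the distinct underlying signals
        from lamconn.connstat import seed_fcs

        T = 60
        ev = np.sin(2 * np.pi * np.arange(T) / 12)
        a = rng.standard_normal(T)
        b = rng.standard_normal(T)
        V, D = 8, 3
        vals = np.zeros((V, D, T))
        vals[:4] = 0.3 * a + 3.0 * ev
        vals[4:] = 0.3 * b + 3.0 * ev
        vals += 0.01 * rng.standard_normal(vals.shape)
        mask = np.ones(V, bool)
        seed_a = np.zeros(V, bool)
        seed_a[:2] = True
        targets = np.zeros(V, bool)
        targets[6:] = True  # group-b targets

        def mean_fcs(v):
            return np.nanmean(seed_fcs(v, seed_a, targets).values[targets])

        pre = mean_fcs(vals)
        post = mean_fcs(regress_evoked(vals, ev, mask))
        # across-seed difference grows after removing the shared response:
        # the a-seed/b-target FCS drops once the common evoked signal is gone
        assert pre - post > 0
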