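"""Temporal/spatial preprocessing: filters, scaling, nuisance regression."""

import numpy as np
import pytest

from boldvar.core import SLOW4, SLOW5, FrequencyBand, band_bin_mask, nyquist
from boldvar.preprocess import (
    NuisanceSet,
    bandpass,
    despike,
    detrend,
    drop_initial_volumes,
    grand_mean_scale,
    motion_exclude,
    regress_nuisance,
    smooth_gaussian,
)
from tests.conftest import make_run

TR = 2.3
T = 125


def sinusoid_run(freq_hz, t=T, tr=TR, shape=(2, 2, 2)):
    ts = np.sin(2 * np.pi * freq_hz * tr * np.arange(t))
    data = np.broadcast_to(ts, shape + (t,)).copy()
    return make_run(data, tr_s=tr)


class TestDropDespikeScale:
    def test_drop_initial_volumes(self):
        run = make_run(np.arange(130.0).reshape(1, 1, 1, 130))
        out = drop_initial_volumes(run, 5)
        assert out.n_t == 125
        assert out.data[0, 0, 0, 0] == 5.0
        assert drop_initial_volumes(run, 0).n_t == 130
        with pytest.raises(ValueError):
            drop_initial_volumes(make_run(np.zeros((1, 1, 1, 4))), 5)

    def test_despike_modifies_exactly_injected_indices(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, size=(3, 3, 2, 125))
        spikes = {(0, 0, 0): [7, 90], (2, 1, 1): [33]}
        for vox, idx in spikes.items():
            for i in idx:
                data[vox + (i,)] += 40.0
        run = make_run(data.copy())
        out = despike(run, z_clip=4.0)
        changed = np.argwhere(np.abs(out.data - data) > 1e-12)
        changed_set = {(tuple(c[:3]), c[3]) for c in changed}
        expected = {(vox, i) for vox, idx in spikes.items() for i in idx}
        assert changed_set == expected

    def test_despike_identity_on_clean_series(self):
        rng = np.random.default_rng(1)
        run = make_run(rng.normal(0, 1, size=(2, 2, 2, 80)))
        out = despike(run)
        assert np.array_equal(out.data, run.data)

    def test_grand_mean_scale(self):
        run = make_run(np.full((2, 2, 1, 30), 500.0))
        out = grand_mean_scale(run, 10000.0)
        assert out.data.mean() == pytest.approx(10000.0)
        assert np.allclose(out.data / run.data, 20.0)
        again = grand_mean_scale(out, 10000.0)
        assert np.allclose(again.data, out.data)
        with pytest.raises(ValueError):
            grand_mean_scale(make_run(np.zeros((1, 1, 1, 30))))


class TestSmoothing:
    def test_fwhm_zero_identity_and_constant_preserved(self):
        rng = np.random.default_rng(2)
        run = make_run(rng.normal(size=(6, 6, 6, 10)))
        assert np.array_equal(smooth_gaussian(run, 0.0).data, run.data)
        const = make_run(np.full((6, 6, 6, 5), 3.7))
        assert np.allclose(smooth_gaussian(const, 6.0).data, 3.7)

    def test_impulse_response_fwhm_about_two_voxels(self):
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        out = smooth_gaussian(make_run(data), fwhm_mm=6.0, voxel_mm=(3, 3, 3)).data[..., 0]
        profile = out[:, 10, 10]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        # linear interpolation of the half-max crossings
        lo = above[0] - (profile[above[0]] - half) / (profile[above[0]] - profile[above[0] - 1])
        hi = above[-1] + (profile[above[-1]] - half) / (profile[above[-1]] - profile[above[-1] + 1])
        assert hi - lo == pytest.approx(2.0, rel=0.1)


class TestDetrend:
    def test_linear_ramp_removed(self):
        ramp = np.linspace(0, 5, 60).reshape(1, 1, 1, 60) + 2.0
        out = detrend(make_run(ramp), order=1)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_sine_recovered_from_sine_plus_ramp(self):
        t = np.arange(T)
        sine = np.sin(2 * np.pi * 0.05 * TR * t)
        data = (sine + 0.03 * t + 1.0).reshape(1, 1, 1, T)
        out = detrend(make_run(data), order=1).data[0, 0, 0]
        assert np.corrcoef(out, sine)[0, 1] > 0.999

    def test_order_zero_is_mean_centering(self):
        rng = np.random.default_rng(3)
        run = make_run(rng.normal(5, 2, size=(2, 2, 1, 40)))
        out = detrend(run, order=0)
        assert np.allclose(out.data, run.data - run.data.mean(axis=-1, keepdims=True))


class TestNuisanceRegression:
    @staticmethod
    def nuisance(t, seed=0, rng=None):
        rng = rng or np.random.default_rng(seed)
        return NuisanceSet(
            motion6=rng.normal(size=(t, 6)),
            csf=rng.normal(size=t),
            wm=rng.normal(size=t),
        )

    def test_global_signal_voxel_fully_removed(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=60)
        data = np.broadcast_to(g, (2, 2, 2, 60)).copy()
        run = make_run(data)
        out = regress_nuisance(run, self.nuisance(60, rng=rng), include_global=True)
        assert np.max(np.abs(out.data)) < 1e-8

    def test_residuals_match_projection_oracle(self):
        """Residuals equal (I - X (X'X)^-1 X') y from an explicit
        normal-equations oracle."""
        rng = np.random.default_rng(5)
        t = 80
        nuis = self.nuisance(t, rng=rng)
        data = rng.normal(size=(3, 2, 1, t))
        run = make_run(data)
        out = regress_nuisance(run, nuis, include_global=False)
        X = np.column_stack([np.ones(t), nuis.motion6, nuis.csf, nuis.wm])
        P = np.eye(t) - X @ np.linalg.inv(X.T @ X) @ X.T
        expected = np.einsum("ts,xyzs->xyzt", P, data)
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        rng = np.random.default_rng(6)
        t = 70
        nuis = self.nuisance(t, rng=rng)
        run = make_run(rng.normal(size=(2, 2, 2, t)))
        out = regress_nuisance(run, nuis, include_global=True)
        X = np.column_stack([np.ones(t), nuis.motion6, nuis.csf, nuis.wm])
        resid = out.in_mask()
        dots = resid @ (X / np.linalg.norm(X, axis=0))
        assert np.max(np.abs(dots)) < 1e-6

    def test_collinear_design_reported(self):
        rng = np.random.default_rng(7)
        t = 50
        nuis = self.nuisance(t, rng=rng)
        nuis.wm = nuis.csf.copy()  # exact collinearity
        run = make_run(rng.normal(size=(1, 1, 1, t)))
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(run, nuis, include_global=False)


class TestBandpass:
    def test_in_band_sinusoid_passes(self):
        # bin-aligned in-band frequency: exact passthrough
        f_bin = 5 / (T * TR)  # ~0.0174 Hz, inside slow5
        run = sinusoid_run(f_bin)
        out = bandpass(run, SLOW5)
        err = np.sqrt(np.mean((out.data - run.data) ** 2)) / run.data.std()
        assert err < 1e-10
        # off-bin frequency: passthrough up to spectral leakage
        run2 = sinusoid_run(0.02)
        out2 = bandpass(run2, SLOW5)
        err2 = np.sqrt(np.mean((out2.data - run2.data) ** 2)) / run2.data.std()
        assert err2 < 0.35

    def test_out_of_band_sinusoid_rejected(self):
        # bin-aligned slow5 frequency: exact rejection by slow4
        run = sinusoid_run(5 / (T * TR))
        out = bandpass(run, SLOW4)
        assert np.sqrt(np.mean(out.data**2)) / run.data.std() < 1e-10
        # off-bin frequency: rejection up to spectral leakage
        run2 = sinusoid_run(0.02)
        out2 = bandpass(run2, SLOW4)
        assert np.sqrt(np.mean(out2.data**2)) / run2.data.std() < 0.2

    def test_white_noise_variance_ratio_matches_bandwidth(self):
        """slow4 retains a fraction of white-noise variance equal to its
        bandwidth share of the Nyquist interval (~0.212 at TR 2.3 s)."""
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(200):
            x = rng.normal(size=(1, 1, 1, T))
            run = make_run(x, tr_s=TR)
            filt = bandpass(run, SLOW4)
            ratios.append(filt.data.var() / x.var())
        keep = band_bin_mask(T, TR, SLOW4)
        expected = (SLOW4.f_hi - SLOW4.f_lo) / nyquist(TR)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.05)

    def test_empty_passband_raises(self):
        run = sinusoid_run(0.02)
        with pytest.raises(ValueError, match="passband"):
            bandpass(run, FrequencyBand("tiny", 0.0201, 0.0202))

    def test_energy_partition_parseval(self):
        """Disjoint bands covering (0, Nyquist] partition the variance of
        the detrended series exactly."""
        rng = np.random.default_rng(9)
        run = detrend(make_run(rng.normal(size=(3, 3, 2, T)), tr_s=TR), order=0)
        edges = [0.0, 0.01, 0.027, 0.073, 0.1, nyquist(TR) + 0.01]
        total = run.in_mask().var(axis=1, ddof=1)
        acc = np.zeros_like(total)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = bandpass(run, FrequencyBand(f"b{lo}", lo + 1e-9, hi))
            acc += sub.in_mask().var(axis=1, ddof=1)
        assert np.allclose(acc, total, rtol=1e-8)

    def test_regression_and_bandpass_commute_on_band_limited_regressors(self):
        """With band-limited nuisance regressors, filtering before or after
        nuisance regression gives the same result (linearity)."""
        rng = np.random.default_rng(10)
        t = T
        from boldvar.synthdata import band_limited_series

        def bl(n):
            return band_limited_series(rng, n, t, TR, SLOW4)

        nuis = NuisanceSet(motion6=bl(6).T, csf=bl(1)[0], wm=bl(1)[0])
        run = make_run(rng.normal(size=(2, 2, 2, t)), tr_s=TR)
        a = bandpass(regress_nuisance(run, nuis, False), SLOW4)
        b = regress_nuisance(bandpass(run, SLOW4), nuis, False)
        # remove the intercept-induced mean difference before comparing
        da = a.data - a.data.mean(-1, keepdims=True)
        db = b.data - b.data.mean(-1, keepdims=True)
        assert np.sqrt(np.mean((da - db) ** 2)) < 1e-6


class TestMotionExclusion:
    def test_strict_threshold(self):
        import pandas as pd

        rec = pd.DataFrame(
            {"group": ["HC", "HC", "AD"], "max_abs_motion": [3.9, 4.0, 4.1]}
        )
        inc, exc, counts = motion_exclude(rec, 4.0)
        assert list(exc["max_abs_motion"]) == [4.1]
        assert len(inc) == 2

    def test_no_exclusions(self):
        import pandas as pd

        rec = pd.DataFrame({"group": ["HC"] * 3, "max_abs_motion": [1.0, 2.0, 3.0]})
        inc, exc, _ = motion_exclude(rec)
        assert len(exc) == 0 and len(inc) == 3

    def test_reported_counts_match_partition(self):
        import pandas as pd

        rng = np.random.default_rng(11)
        rec = pd.DataFrame(
            {
                "group": rng.choice(["HC", "aMCI", "AD"], size=124),
                "max_abs_motion": rng.exponential(2.0, size=124),
            }
        )
        inc, exc, counts = motion_exclude(rec, 4.0)
        assert counts["included"].sum() == len(inc)
        assert counts["excluded"].sum() == len(exc)
        assert len(inc) + len(exc) == 124
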