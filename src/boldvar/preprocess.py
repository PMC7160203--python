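"""Preprocessing operations for the two denoising arms.

The GSR arm follows the classic nuisance-regression pipeline: drop initial
volumes, despike, grand-mean scale, smooth, band-limit/detrend, then
regress out CSF, WM, six motion parameters and the whole-brain global
signal.  The ICA arm decomposes each run into spatial independent
components, scores each component with five bounded noise features,
selects a rejection threshold maximising the balance ratio
(3*TPR + TNR)/4 on a labelled training set, and removes the flagged
components non-aggressively.

All temporal filters are zero-phase DFT brick-wall filters, so band
supports are exact and variance partitions across disjoint bands hold to
numerical precision (Parseval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BoldRun, FrequencyBand, NetworkMasks, band_bin_mask, nyquist

__all__ = [
    "NuisanceSet",
    "ICAComponentSet",
    "FixThresholdResult",
    "IcaConvergenceError",
    "drop_initial_volumes",
    "despike",
    "grand_mean_scale",
    "smooth_gaussian",
    "detrend",
    "regress_nuisance",
    "bandpass",
    "decompose_ica",
    "score_components",
    "select_fix_threshold",
    "remove_components",
    "motion_exclude",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceSet:
    """Nuisance regressors for one run.

    ``global_signal`` may be None, in which case it is recomputed as the
    mean in-mask time series when global-signal regression is requested.
    """

    motion6: np.ndarray  # (t, 6): translations (mm) and rotations (rad)
    csf: np.ndarray
    wm: np.ndarray
    global_signal: np.ndarray | None = None

    def validate(self, n_t: int) -> None:
        if self.motion6.shape != (n_t, 6):
            raise ValueError(f"motion6 must have shape ({n_t}, 6)")
        for name in ("csf", "wm"):
            if len(getattr(self, name)) != n_t:
                raise ValueError(f"{name} regressor length must equal t={n_t}")
        if self.global_signal is not None and len(self.global_signal) != n_t:
            raise ValueError("global_signal length must equal t")


@dataclass
class ICAComponentSet:
    """Spatial-ICA decomposition of a run.

    ``spatial_maps`` has shape (k, x, y, z) and ``timecourses`` (k, t); the
    run is approximated by sum_i map_i (outer) tc_i plus the per-voxel
    temporal mean.
    """

    spatial_maps: np.ndarray
    timecourses: np.ndarray
    mean_map: np.ndarray
    brain_mask: np.ndarray
    tr_s: float
    labels: list | None = None
    scores: np.ndarray | None = None
    reconstruction_rmse: float | None = None

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    def __post_init__(self) -> None:
        if self.spatial_maps.shape[0] != self.timecourses.shape[0]:
            raise ValueError("spatial map and timecourse counts disagree")


@dataclass
class FixThresholdResult:
    """Chosen component-rejection threshold and its operating point."""

    threshold: float
    tpr: float
    tnr: float
    balance_ratio: float

    def __post_init__(self) -> None:
        for v in (self.tpr, self.tnr, self.balance_ratio):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("rates must lie in [0, 1]")


class IcaConvergenceError(RuntimeError):
    def __init__(self, attempts):
        self.attempts = attempts
        super().__init__(f"ICA failed to converge after {len(attempts)} attempts: {attempts}")


# ---------------------------------------------------------------------------
# Elementary steps


def drop_initial_volumes(run: BoldRun, n: int = 5) -> BoldRun:
    """Discard the first ``n`` volumes (scanner magnetisation settling)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if run.n_t <= n:
        raise ValueError(f"cannot drop {n} volumes from a run of length {run.n_t}")
    if n == 0:
        return run.with_data(run.data, "drop_initial_volumes(0)")
    return run.with_data(run.data[..., n:], f"drop_initial_volumes({n})")


def despike(run: BoldRun, z_clip: float = 4.0) -> BoldRun:
    """Winsorise per-voxel outliers beyond ``z_clip`` robust z-scores.

    The robust z-score uses each voxel's temporal median and MAD (scaled to
    be consistent with the normal SD).  Voxels with zero MAD are left
    untouched.
    """
    mat = run.in_mask()
    med = np.median(mat, axis=1, keepdims=True)
    mad = np.median(np.abs(mat - med), axis=1, keepdims=True) * 1.4826
    ok = mad[:, 0] > 0
    lo = med - z_clip * mad
    hi = med + z_clip * mad
    out = mat.copy()
    out[ok] = np.clip(mat[ok], lo[ok], hi[ok])
    return run.set_in_mask(out, f"despike(z_clip={z_clip})")


def grand_mean_scale(run: BoldRun, target: float = 10000.0) -> BoldRun:
    """Scale the run so the in-mask spatiotemporal mean equals ``target``."""
    gm = float(run.in_mask().mean())
    if gm <= 0:
        raise ValueError(f"grand mean must be positive, got {gm}")
    return run.with_data(run.data * (target / gm), f"grand_mean_scale({target})")


def smooth_gaussian(
    run: BoldRun, fwhm_mm: float = 6.0, voxel_mm: tuple | None = None
) -> BoldRun:
    """Spatial-only Gaussian smoothing of each volume."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return run.with_data(run.data, "smooth_gaussian(0)")
    voxel_mm = voxel_mm if voxel_mm is not None else run.voxel_mm
    sigma_vox = [fwhm_mm * _FWHM_TO_SIGMA / v for v in voxel_mm]
    out = ndimage.gaussian_filter(run.data, sigma=tuple(sigma_vox) + (0.0,), mode="nearest")
    return run.with_data(out, f"smooth_gaussian(fwhm={fwhm_mm}mm)")


def detrend(run: BoldRun, order: int = 1) -> BoldRun:
    """Remove a least-squares polynomial trend of given order per voxel."""
    n_t = run.n_t
    if n_t <= order + 1:
        raise ValueError(f"t={n_t} too short for order-{order} detrend")
    t = np.linspace(-1.0, 1.0, n_t)
    X = np.polynomial.polynomial.polyvander(t, order)  # (t, order+1)
    mat = run.in_mask()
    beta, *_ = np.linalg.lstsq(X, mat.T, rcond=None)
    resid = mat - (X @ beta).T
    return run.set_in_mask(resid, f"detrend(order={order})")


def _design_matrix(run: BoldRun, nuisance: NuisanceSet, include_global: bool):
    n_t = run.n_t
    nuisance.validate(n_t)
    cols = [np.ones(n_t)]
    names = ["intercept"]
    for i in range(6):
        cols.append(nuisance.motion6[:, i])
        names.append(f"motion{i + 1}")
    cols.append(np.asarray(nuisance.csf, dtype=float))
    names.append("csf")
    cols.append(np.asarray(nuisance.wm, dtype=float))
    names.append("wm")
    if include_global:
        g = nuisance.global_signal
        if g is None:
            g = run.in_mask().mean(axis=0)
        cols.append(np.asarray(g, dtype=float))
        names.append("global")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via rank-revealing QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    return X, names


def regress_nuisance(
    run: BoldRun, nuisance: NuisanceSet, include_global: bool
) -> BoldRun:
    """OLS-residualise every in-mask voxel on the nuisance design.

    The design is [intercept, 6 motion parameters, CSF, WM] plus the
    whole-brain global signal when ``include_global`` is True (the GSR arm).
    """
    X, _ = _design_matrix(run, nuisance, include_global)
    mat = run.in_mask()
    beta, *_ = np.linalg.lstsq(X, mat.T, rcond=None)
    resid = mat - (X @ beta).T
    step = "regress_nuisance(global=%s)" % include_global
    return run.set_in_mask(resid, step)


def bandpass(run: BoldRun, band: FrequencyBand) -> BoldRun:
    """Zero-phase brick-wall band-pass via the discrete Fourier transform.

    rfft coefficients with ``f_lo <= f <= min(f_hi, nyquist)`` are kept
    (DC only when ``f_lo == 0``); everything else is zeroed.
    """
    if run.n_t < 20:
        raise ValueError("bandpass requires at least 20 timepoints")
    keep = band_bin_mask(run.n_t, run.tr_s, band)
    if not keep[1:].any() and band.f_lo > 0:
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz has an empty passband "
            f"at t={run.n_t}, TR={run.tr_s}s"
        )
    mat = run.in_mask()
    spec = np.fft.rfft(mat, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=run.n_t, axis=1)
    return run.set_in_mask(out, f"bandpass({band.name})")


# ---------------------------------------------------------------------------
# ICA arm


def _highpass_matrix(mat: np.ndarray, tr_s: float, cutoff_hz: float) -> np.ndarray:
    n_t = mat.shape[1]
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    keep = freqs >= cutoff_hz - 1e-12
    keep[0] = False
    spec = np.fft.rfft(mat, axis=1)
    spec[:, ~keep] = 0.0
    return np.fft.irfft(spec, n=n_t, axis=1)


def decompose_ica(
    run: BoldRun,
    highpass_hz: float = 0.01,
    n_components: int | str = "auto",
    seed: int = 0,
    max_attempts: int = 3,
) -> ICAComponentSet:
    """Single-session spatial ICA of one run.

    The in-mask voxel x time matrix is high-pass filtered, the
    dimensionality is chosen as the smallest k explaining >= 90% of the
    (filtered) variance, capped at t/4, and FastICA estimates k spatial
    sources with their mixing time courses.  Non-convergent fits are
    retried with fresh seeds; persistent failure raises
    :class:`IcaConvergenceError` carrying the attempt log.
    """
    from sklearn.decomposition import FastICA

    if run.n_t < 30:
        raise ValueError("decompose_ica requires at least 30 timepoints")
    mat = run.in_mask()
    mean_tc = mat.mean(axis=1)
    hp = _highpass_matrix(mat, run.tr_s, highpass_hz)

    if n_components == "auto":
        # explained-variance rule on the temporal covariance spectrum
        u_s = np.linalg.svd(hp, compute_uv=False)
        var = u_s**2
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, 0.90) + 1)
        k = max(2, min(k, run.n_t // 4))
    else:
        k = int(n_components)
        if k < 2:
            raise ValueError("n_components must be >= 2")

    attempts = []
    for attempt in range(max_attempts):
        ica_seed = seed + 1000 * attempt
        # deflation extracts sources one at a time; on low-rank fixtures it
        # converges where the symmetric update stalls
        ica = FastICA(
            n_components=k,
            random_state=ica_seed,
            whiten="unit-variance",
            algorithm="deflation",
            max_iter=500,
            tol=1e-3,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("error", message=".*did not converge.*")
            try:
                S = ica.fit_transform(hp)  # (voxels, k) spatial sources
            except Warning as w:  # ConvergenceWarning promoted to error
                attempts.append(f"seed={ica_seed}: {w}")
                continue
        A = ica.mixing_  # (t, k)
        break
    else:
        raise IcaConvergenceError(attempts)

    # normalise each spatial map to unit SD, folding scale into timecourses
    map_sd = S.std(axis=0, ddof=0)
    map_sd[map_sd == 0] = 1.0
    S = S / map_sd
    A = A * map_sd

    recon = S @ A.T + ica.mean_
    rmse = float(np.sqrt(np.mean((recon - hp) ** 2)))

    maps = np.zeros((k,) + run.spatial_shape)
    maps[:, run.brain_mask] = S.T
    mean_map = np.zeros(run.spatial_shape)
    mean_map[run.brain_mask] = mean_tc
    return ICAComponentSet(
        spatial_maps=maps,
        timecourses=A.T,
        mean_map=mean_map,
        brain_mask=run.brain_mask,
        tr_s=run.tr_s,
        reconstruction_rmse=rmse,
    )


def _robust_max_z(tc: np.ndarray) -> float:
    med = np.median(tc)
    mad = np.median(np.abs(tc - med)) * 1.4826
    if mad == 0:
        return 0.0
    return float(np.max(np.abs(tc - med)) / mad)


#: Feature weights of the component noise score (clipped to 100).
SCORE_WEIGHTS = {
    "spikes": 40.0,
    "edge": 25.0,
    "nongrey": 25.0,
    "highfreq": 60.0,
    "rough": 30.0,
}


def component_features(
    components: ICAComponentSet, masks: NetworkMasks, tr_s: float | None = None
) -> pd.DataFrame:
    """Five bounded noise features per component (each in [0, 1]).

    spikes: time-series spikiness, (max robust z - 3)/5 clipped;
    edge: squared-map energy fraction on the brain-edge shell;
    nongrey: energy fraction in in-brain non-grey voxels;
    highfreq: spectral power fraction above 0.1 Hz;
    rough: one minus the spatial smoothness (correlation between the map
    and its lightly smoothed version) — sparse alternating-sign maps score
    near 1, coherent blobs near 0.
    """
    tr = tr_s if tr_s is not None else components.tr_s
    brain = masks.brain_mask
    edge_shell = brain & ~ndimage.binary_erosion(brain)
    nongrey = brain & ~masks.grey_mask
    rows = []
    for m, tc in zip(components.spatial_maps, components.timecourses):
        energy = m[brain] ** 2
        tot = energy.sum()
        if tot == 0 and np.all(tc == 0):
            rows.append(dict.fromkeys(SCORE_WEIGHTS, 0.0))
            continue
        f_spike = float(np.clip((_robust_max_z(tc) - 3.0) / 5.0, 0.0, 1.0))
        f_edge = float(m[edge_shell] @ m[edge_shell] / tot) if tot > 0 else 0.0
        f_nongrey = float(m[nongrey] @ m[nongrey] / tot) if tot > 0 else 0.0
        spec = np.abs(np.fft.rfft(tc - tc.mean())) ** 2
        freqs = np.fft.rfftfreq(len(tc), d=tr)
        p_tot = spec.sum()
        f_hf = float(spec[freqs > 0.1].sum() / p_tot) if p_tot > 0 else 0.0
        if tot > 0:
            sm = ndimage.gaussian_filter(m, sigma=1.0)
            a, b = m[brain], sm[brain]
            denom = a.std() * b.std()
            smooth_corr = float(np.corrcoef(a, b)[0, 1]) if denom > 0 else 0.0
            f_rough = float(np.clip(1.0 - max(smooth_corr, 0.0), 0.0, 1.0))
        else:
            f_rough = 0.0
        rows.append(
            {
                "spikes": f_spike,
                "edge": f_edge,
                "nongrey": f_nongrey,
                "highfreq": f_hf,
                "rough": f_rough,
            }
        )
    return pd.DataFrame(rows)


def score_components(
    components: ICAComponentSet, masks: NetworkMasks, tr_s: float | None = None
) -> np.ndarray:
    """Noise score in [0, 100] per component: a clipped weighted sum of the
    five bounded features (monotone non-decreasing in every feature)."""
    feats = component_features(components, masks, tr_s)
    raw = sum(SCORE_WEIGHTS[c] * feats[c].to_numpy() for c in SCORE_WEIGHTS)
    return np.clip(raw, 0.0, 100.0)


def select_fix_threshold(scores: np.ndarray, truth: list) -> FixThresholdResult:
    """Exhaustive sweep for the rejection threshold maximising the balance
    ratio (3*TPR + TNR)/4.

    Components with score > threshold are rejected as noise.  TPR is the
    fraction of true signal components kept; TNR the fraction of true
    noise components rejected.  Ties favour the larger threshold, i.e. the
    more conservative rejection that keeps more components.  With no noise
    components TNR is defined as 1 at every threshold.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    is_signal = truth == "signal"
    if not is_signal.any():
        raise ValueError("at least one signal-labelled component is required")
    n_sig = int(is_signal.sum())
    n_noise = int((~is_signal).sum())

    candidates = np.concatenate([[-np.inf], np.unique(scores)])
    best = None
    for thr in candidates:
        kept = scores <= thr
        tpr = float((kept & is_signal).sum() / n_sig)
        tnr = float((~kept & ~is_signal).sum() / n_noise) if n_noise else 1.0
        ratio = (3.0 * tpr + tnr) / 4.0
        if best is None or ratio >= best.balance_ratio - 1e-12:
            if best is None or ratio > best.balance_ratio + 1e-12 or thr > best.threshold:
                best = FixThresholdResult(float(thr), tpr, tnr, ratio)
    return best


def remove_components(
    run: BoldRun, components: ICAComponentSet, noise_ids: list
) -> BoldRun:
    """Non-aggressive removal of the listed noise components.

    All component time courses are regressed jointly against every voxel
    series and only the part uniquely attributed to the noise components is
    subtracted, so variance shared with signal components is preserved.
    Removal is a projection and therefore idempotent.
    """
    noise_ids = list(noise_ids)
    k = components.n_components
    if any(i < 0 or i >= k for i in noise_ids):
        raise ValueError(f"noise_ids must index components 0..{k - 1}")
    if len(set(noise_ids)) == k:
        raise ValueError("refusing to remove all components")
    if not noise_ids:
        return run.with_data(run.data, "remove_components([])")

    T = components.timecourses.T  # (t, k)
    X = np.column_stack([np.ones(run.n_t), T])
    mat = run.in_mask()  # (v, t)
    beta, *_ = np.linalg.lstsq(X, mat.T, rcond=None)  # (k+1, v)
    cols = [i + 1 for i in noise_ids]
    cleaned = mat - (X[:, cols] @ beta[cols]).T
    return run.set_in_mask(cleaned, f"remove_components({sorted(noise_ids)})")


# ---------------------------------------------------------------------------
# Sample-level QC


def motion_exclude(records: pd.DataFrame, threshold_mm: float = 4.0):
    """Partition subjects by the maximum-absolute-motion rule (strict >).

    Returns ``(included, excluded, counts)`` where counts is a per-group
    DataFrame of included/excluded tallies.
    """
    if "max_abs_motion" not in records.columns:
        raise ValueError("records must carry a max_abs_motion column")
    excl = records["max_abs_motion"] > threshold_mm
    included = records.loc[~excl].copy()
    excluded = records.loc[excl].copy()
    counts = (
        pd.DataFrame(
            {
                "included": included.groupby("group").size(),
                "excluded": excluded.groupby("group").size(),
            }
        )
        .fillna(0)
        .astype(int)
    )
    return included, excluded, counts
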