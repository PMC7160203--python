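"""Voxelwise variability maps: SD, fractional SD and spatially z-scored fSD.

The variability index is the temporal standard deviation of the
band-filtered BOLD signal.  Fractional SD (fSD) divides each sub-band's SD
by the whole-band SD, giving the band's share of total fluctuation;
z-fSD standardises each subject's fSD map spatially across in-brain
voxels, so group comparisons are on a common within-subject scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SLOW4, SLOW5, BoldRun, FrequencyBand, band_bin_mask

__all__ = [
    "VariabilityMaps",
    "sd_map",
    "fsd_map",
    "zscore_spatial",
    "compute_zfsd",
]


@dataclass
class VariabilityMaps:
    """Per-band variability volumes for one subject.

    ``mask_used`` excludes voxels whose whole-band SD is numerically zero
    (no fSD is defined there); out-of-mask voxels are NaN in every map.
    """

    band: FrequencyBand
    sd: np.ndarray
    fsd: np.ndarray
    zfsd: np.ndarray
    mask_used: np.ndarray


def sd_map(run: BoldRun, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel temporal sample SD (denominator t - 1); NaN outside mask."""
    if run.n_t < 2:
        raise ValueError("sd_map requires at least 2 timepoints")
    mask = mask if mask is not None else run.brain_mask
    out = np.full(run.spatial_shape, np.nan)
    out[mask] = run.data[mask].std(axis=1, ddof=1)
    return out


def fsd_map(
    run_band: BoldRun, run_whole: BoldRun, mask: np.ndarray | None = None
):
    """Fractional SD: sd(sub-band) / sd(whole band), voxelwise.

    Voxels whose whole-band SD falls below 1e-8 times the in-mask grand SD
    are removed from the usable mask (their ratio is undefined).  Returns
    ``(fsd, mask_used)``.
    """
    if run_band.spatial_shape != run_whole.spatial_shape or run_band.n_t != run_whole.n_t:
        raise ValueError("band and whole-band runs are misaligned")
    mask = mask if mask is not None else run_whole.brain_mask
    sd_b = sd_map(run_band, mask)
    sd_w = sd_map(run_whole, mask)
    grand = np.nanmean(sd_w[mask])
    eps = 1e-8 * grand if grand > 0 else 0.0
    ok = mask & (np.nan_to_num(sd_w) > eps)
    out = np.full(run_band.spatial_shape, np.nan)
    out[ok] = sd_b[ok] / sd_w[ok]
    return out, ok


def zscore_spatial(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardise a 3D map across in-mask voxels (denominator n - 1)."""
    vals = vol[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite in-mask voxels to z-score")
    mu = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("spatially constant map: z-scoring undefined")
    out = np.full(vol.shape, np.nan)
    out[mask] = (vol[mask] - mu) / sd
    return out


def compute_zfsd(
    run_preprocessed: BoldRun,
    bands: list[FrequencyBand] = (SLOW4, SLOW5),
    mask: np.ndarray | None = None,
) -> dict[str, VariabilityMaps]:
    """Band-pass, SD, fSD and spatial z-scoring for each requested band.

    The whole-band reference is the detrended (mean-free) input series,
    computed once; every band shares the same usable mask (the
    intersection rule), so per-subject z-maps are comparable across bands.
    """
    mask = mask if mask is not None else run_preprocessed.brain_mask
    shape = run_preprocessed.spatial_shape
    n_t = run_preprocessed.n_t
    tr = run_preprocessed.tr_s

    # band SDs are computed in the frequency domain: for a mean-free series
    # the sample variance restricted to a set of rfft bins is
    # 2 * sum |X_k|^2 / (n * (n - 1)) (Parseval; no Nyquist bin for odd n,
    # and the Nyquist term's factor-2 error is negligible at these lengths),
    # which equals the variance of the brick-wall-filtered series exactly.
    mat = run_preprocessed.data[mask]
    mat = mat - mat.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(mat, axis=1)) ** 2
    spec[:, 0] = 0.0
    if n_t % 2 == 0:
        spec[:, -1] *= 0.5  # Nyquist bin is not doubled
    scale = 2.0 / (n_t * (n_t - 1))

    sd_w_flat = np.sqrt(spec.sum(axis=1) * scale)
    sd_w = np.full(shape, np.nan)
    sd_w[mask] = sd_w_flat
    grand = sd_w_flat.mean()
    eps = 1e-8 * grand if grand > 0 else 0.0
    mask_used = mask & (np.nan_to_num(sd_w) > eps)
    ok_flat = sd_w[mask_used]

    out: dict[str, VariabilityMaps] = {}
    for band in bands:
        keep = band_bin_mask(n_t, tr, band)
        keep = keep.copy()
        keep[0] = False
        sd_b = np.full(shape, np.nan)
        sd_b[mask] = np.sqrt(spec[:, keep].sum(axis=1) * scale)
        fsd = np.full(shape, np.nan)
        fsd[mask_used] = sd_b[mask_used] / sd_w[mask_used]
        zfsd = zscore_spatial(fsd, mask_used)
        sd_b[~mask_used] = np.nan
        out[band.name] = VariabilityMaps(
            band=band, sd=sd_b, fsd=fsd, zfsd=zfsd, mask_used=mask_used
        )
    return out
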