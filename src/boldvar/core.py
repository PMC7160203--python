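"""Shared domain types for the BOLD-variability pipeline.

The analysis operates on single-subject 4D resting-state runs (`BoldRun`),
decomposes them into canonical low-frequency bands (`FrequencyBand`), and
relates voxelwise variability to diagnostic group and phenotype
(`SubjectRecord`).  Network geometry for the synthetic phantom and for
cluster labelling is carried by `NetworkMasks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BoldRun",
    "FrequencyBand",
    "NetworkMasks",
    "SubjectRecord",
    "SLOW4",
    "SLOW5",
    "STANDARD_LOW",
    "PHENO_COLUMNS",
    "GROUPS",
    "band_bin_mask",
    "nyquist",
]

#: Diagnostic groups, in severity order (reference group first).
GROUPS = ("HC", "aMCI", "AD")

#: Fixed phenotype-table schema (TSV header order).
PHENO_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "gmv",
    "max_abs_motion",
    "cevd",
    "cognition_baseline",
    "cognition_year2",
    "hippocampal_volume",
]


@dataclass(frozen=True)
class FrequencyBand:
    """A closed frequency interval [f_lo, f_hi] in Hz.

    ``f_hi`` may exceed the Nyquist frequency of a given run; the effective
    upper edge is always ``min(f_hi, nyquist)``.  The whole-band variant
    (nominally 0–0.25 Hz) therefore reduces to the full detrended spectrum
    at TR = 2.3 s, where Nyquist is ~0.217 Hz.
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges: [{self.f_lo}, {self.f_hi}]")


SLOW4 = FrequencyBand("slow4", 0.027, 0.073)
SLOW5 = FrequencyBand("slow5", 0.01, 0.027)
STANDARD_LOW = FrequencyBand("standard_low", 0.009, 0.1)


def nyquist(tr_s: float) -> float:
    return 0.5 / tr_s


def band_bin_mask(n_t: int, tr_s: float, band: FrequencyBand) -> np.ndarray:
    """Boolean mask over rfft bins retained by a brick-wall filter.

    Bins with ``f_lo <= f <= min(f_hi, nyquist)`` are kept; the DC bin is
    kept only when ``f_lo == 0``.  A small tolerance guards against
    floating-point edge effects at exact band boundaries.
    """
    freqs = np.fft.rfftfreq(n_t, d=tr_s)
    hi = min(band.f_hi, nyquist(tr_s))
    eps = 1e-12
    keep = (freqs >= band.f_lo - eps) & (freqs <= hi + eps)
    if band.f_lo > 0:
        keep[0] = False
    return keep


@dataclass
class BoldRun:
    """One subject's 4D resting-state time series.

    data has shape (x, y, z, t) in arbitrary BOLD units; ``brain_mask`` is a
    boolean 3D array of the same spatial shape.  ``provenance`` records the
    ordered list of preprocessing steps applied so far.
    """

    data: np.ndarray
    tr_s: float
    brain_mask: np.ndarray
    provenance: list = field(default_factory=list)
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    nuisance: object = None  # optional NuisanceSet attached by the phantom

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BoldRun.data must be 4D (x, y, z, t)")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape must match spatial shape of data")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_t(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, step: str) -> "BoldRun":
        """Return a new run with replaced data and a provenance entry."""
        return replace(self, data=data, provenance=self.provenance + [step])

    def in_mask(self) -> np.ndarray:
        """In-mask voxel matrix, shape (n_voxels, t)."""
        return self.data[self.brain_mask]

    def set_in_mask(self, mat: np.ndarray, step: str) -> "BoldRun":
        out = self.data.copy()
        out[self.brain_mask] = mat
        return self.with_data(out, step)


@dataclass
class NetworkMasks:
    """Disjoint network parcels of the phantom brain.

    Five named parcels plus a generic grey-matter `background` block; the
    brain mask is their union plus a padding rind of non-grey in-brain
    voxels (the phantom's stand-in for WM/CSF/edge tissue).
    """

    dmn_posterior: np.ndarray
    dmn_anterior: np.ndarray
    sn: np.ndarray
    vn: np.ndarray
    hippocampus: np.ndarray
    background: np.ndarray
    brain_mask: np.ndarray

    NETWORK_NAMES = (
        "dmn_posterior",
        "dmn_anterior",
        "sn",
        "vn",
        "hippocampus",
        "background",
    )

    def named(self) -> dict:
        return {name: getattr(self, name) for name in self.NETWORK_NAMES}

    @property
    def grey_mask(self) -> np.ndarray:
        """Union of all parcels: the phantom's grey matter."""
        out = np.zeros_like(self.brain_mask)
        for m in self.named().values():
            out |= m
        return out

    def validate(self) -> None:
        total = np.zeros(self.brain_mask.shape, dtype=int)
        for name, m in self.named().items():
            if m.shape != self.brain_mask.shape:
                raise ValueError(f"mask {name} shape mismatch")
            if not np.all(self.brain_mask[m]):
                raise ValueError(f"mask {name} extends outside brain_mask")
            total += m.astype(int)
        if total.max() > 1:
            raise ValueError("network masks overlap")


@dataclass
class SubjectRecord:
    """Phenotype row for one subject."""

    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    gmv: float
    max_abs_motion: float
    cevd: str
    cognition_baseline: float
    cognition_year2: float  # NaN when the year-2 visit is missing
    hippocampal_volume: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name in ("education", "gmv", "hippocampal_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
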