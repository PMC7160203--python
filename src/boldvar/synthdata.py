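"""Seeded synthetic resting-state cohorts for the variability pipeline.

The phantom emulates the statistical structure the analysis assumes rather
than anatomy: each grey-matter voxel carries a sum of spectrally disjoint
band-limited oscillations (slow5, slow4, and a high-frequency remainder)
whose standard deviation is set per (group, network, band), plus an
optional shared "global" nuisance signal with group- and network-specific
coupling, linear drift, motion-spike artifacts, and white noise.

Band-limited processes are generated in the frequency domain with flat
amplitude inside the band and uniform random phases, so the injected
per-voxel population SD is exact and fractional-SD invariants are
analytically checkable.

Phenotypes (cognition, hippocampal volume) are generated from each
subject's injected posterior-DMN variability factor, so brain-behaviour
associations downstream have a known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GROUPS,
    PHENO_COLUMNS,
    SLOW4,
    SLOW5,
    BoldRun,
    FrequencyBand,
    NetworkMasks,
    SubjectRecord,
    band_bin_mask,
)

__all__ = [
    "PhantomConfig",
    "ConfigurationError",
    "make_masks",
    "simulate_subject",
    "simulate_cohort",
    "make_labeled_components",
    "published_cohort_config",
]


class ConfigurationError(ValueError):
    """Raised when a phantom configuration is internally inconsistent."""


def _default_band_power() -> dict:
    # Baseline oscillatory SD per band (arbitrary BOLD units).  The "high"
    # band fills the spectrum above slow4 so whole-band SD is never
    # dominated by the bands under study.
    return {"slow5": 1.0, "slow4": 1.0, "high": 0.5}


def _default_effect_table() -> dict:
    # Qualitative group pattern of the disease phantom: higher posterior-DMN
    # and visual-network variability with lower salience-network variability
    # in aMCI, and reduced posterior-DMN variability in AD.  Factors are
    # band-specific on purpose: fractional SD is invariant to broadband
    # scaling, so only relative band changes are observable downstream.
    return {
        ("aMCI", "dmn_posterior", "slow5"): 1.5,
        ("aMCI", "vn", "slow5"): 1.3,
        ("aMCI", "sn", "slow5"): 0.67,
        ("aMCI", "dmn_posterior", "slow4"): 1.2,
        ("aMCI", "sn", "slow4"): 0.8,
        ("AD", "dmn_posterior", "slow4"): 0.7,
        ("AD", "dmn_posterior", "slow5"): 0.8,
    }


@dataclass
class PhantomConfig:
    """Generative knobs of the synthetic cohort.

    ``effect_table`` maps (group, network, band name) to a multiplicative SD
    factor (missing keys default to 1).  ``gs_coupling`` maps (group,
    network) to the weight of the shared global signal added to that
    network's voxels (missing keys default to 0); the global signal is
    band-limited to ``gs_band``.
    """

    grid_shape: tuple = (24, 24, 18)
    n_volumes: int = 125
    tr_s: float = 2.3
    groups: dict = field(default_factory=lambda: {"HC": 12, "aMCI": 12, "AD": 12})
    band_power: dict = field(default_factory=_default_band_power)
    effect_table: dict = field(default_factory=_default_effect_table)
    gs_coupling: dict = field(default_factory=dict)
    gs_band: FrequencyBand = SLOW4
    baseline: float = 100.0  # mean BOLD intensity inside the brain
    network_coherence: float = 0.5
    noise_sd: float = 0.5
    motion_spike_rate: float = 1.0
    spike_amp: float = 6.0
    drift_amp: float = 1.0
    cognition_slope: float = 5.0
    decline_slope: float = 3.0
    cognition_noise_sd: float = 0.5
    decline_noise_sd: float = 0.4
    hippocampus_slope: float = 800.0
    hippocampus_noise_sd: float = 150.0
    factor_jitter_sd: float = 0.2
    missing_year2_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be positive")
        if self.n_volumes < 20:
            raise ConfigurationError("n_volumes must be at least 20")
        for g in self.groups:
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group label {g!r}")
        if any(n < 0 for n in self.groups.values()):
            raise ConfigurationError("group sizes must be non-negative")
        if any(sd < 0 for sd in self.band_power.values()):
            raise ConfigurationError("band powers must be non-negative")
        if any(f <= 0 for f in self.effect_table.values()):
            raise ConfigurationError("effect factors must be positive")
        if self.noise_sd < 0 or self.drift_amp < 0 or self.motion_spike_rate < 0:
            raise ConfigurationError("noise, drift and spike rates must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.groups.values())

    def generation_bands(self) -> dict:
        """Named FrequencyBand for each generated band."""
        nyq = 0.5 / self.tr_s
        known = {
            "slow5": SLOW5,
            "slow4": SLOW4,
            "high": FrequencyBand("high", SLOW4.f_hi, nyq + 1.0),
        }
        out = {}
        for name in self.band_power:
            if name not in known:
                raise ConfigurationError(f"unknown generation band {name!r}")
            out[name] = known[name]
        return out


def published_cohort_config(**overrides) -> PhantomConfig:
    """Preset with the study's included-sample group sizes (48/98/96)."""
    cfg = PhantomConfig(groups={"HC": 48, "aMCI": 98, "AD": 96}, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# Geometry


def make_masks(config: PhantomConfig) -> NetworkMasks:
    """Deterministic disjoint network parcels on the phantom grid.

    The interior of the grid is split into a 3 x 2 lattice of cells; each
    cell hosts one rectangular parcel occupying ~60% of the cell per axis,
    which forces pairwise disjointness and leaves a non-grey rind inside
    the brain mask.
    """
    nx, ny, nz = config.grid_shape
    margins = [max(1, round(0.12 * d)) for d in (nx, ny, nz)]
    inner_lo = margins
    inner_hi = [d - m for d, m in zip((nx, ny, nz), margins)]
    inner_dims = [hi - lo for lo, hi in zip(inner_lo, inner_hi)]
    if min(inner_dims) < 2:
        raise ConfigurationError(f"grid {config.grid_shape} too small for network masks")

    def cell_block(ix: int, iy: int) -> tuple:
        # cell (ix of 3 along x, iy of 2 along y), full inner extent in z
        x0 = inner_lo[0] + ix * inner_dims[0] // 3
        x1 = inner_lo[0] + (ix + 1) * inner_dims[0] // 3
        y0 = inner_lo[1] + iy * inner_dims[1] // 2
        y1 = inner_lo[1] + (iy + 1) * inner_dims[1] // 2
        z0, z1 = inner_lo[2], inner_hi[2]
        out = []
        for lo, hi in ((x0, x1), (y0, y1), (z0, z1)):
            span = hi - lo
            keep = max(1, int(0.6 * span))
            pad = (span - keep) // 2
            out.append((lo + pad, lo + pad + keep))
        return tuple(out)

    cells = [(0, 0), (2, 0), (0, 1), (2, 1), (1, 0), (1, 1)]
    masks = {}
    for name, (ix, iy) in zip(NetworkMasks.NETWORK_NAMES, cells):
        m = np.zeros(config.grid_shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = cell_block(ix, iy)
        m[x0:x1, y0:y1, z0:z1] = True
        if m.sum() < 30:
            raise ConfigurationError(
                f"grid {config.grid_shape} too small: mask {name} has {int(m.sum())} voxels"
            )
        masks[name] = m

    brain = np.zeros(config.grid_shape, dtype=bool)
    pad_lo = [max(0, lo - 1) for lo in inner_lo]
    pad_hi = [min(d, hi + 1) for d, hi in zip((nx, ny, nz), inner_hi)]
    brain[pad_lo[0]:pad_hi[0], pad_lo[1]:pad_hi[1], pad_lo[2]:pad_hi[2]] = True

    out = NetworkMasks(brain_mask=brain, **masks)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Signal generation


def band_limited_series(
    rng: np.random.Generator,
    n_rows: int,
    n_t: int,
    tr_s: float,
    band: FrequencyBand,
) -> np.ndarray:
    """Rows of unit-population-SD band-limited series (flat amplitude,
    uniform random phases inside the band's rfft bins)."""
    keep = band_bin_mask(n_t, tr_s, band)
    keep = keep.copy()
    keep[0] = False  # oscillatory content only
    m = int(keep.sum())
    if m == 0:
        raise ConfigurationError(
            f"band {band.name} has no DFT support at n={n_t}, TR={tr_s}"
        )
    amp = n_t / np.sqrt(2.0 * m)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_rows, m))
    spec = np.zeros((n_rows, n_t // 2 + 1), dtype=complex)
    spec[:, keep] = amp * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n_t, axis=-1)


@dataclass
class NuisanceTraces:
    """Simulated nuisance regressors recorded alongside a run."""

    motion6: np.ndarray  # (t, 6)
    csf: np.ndarray
    wm: np.ndarray


def simulate_subject(
    record: SubjectRecord,
    masks: NetworkMasks,
    config: PhantomConfig,
    seed: int,
    subject_factor: float = 1.0,
) -> BoldRun:
    """Generate one subject's 4D run.

    ``subject_factor`` is an extra multiplicative SD factor applied to the
    posterior-DMN parcel in every band; cohorts use it to inject
    between-subject variability that phenotypes can couple to.
    """
    if record.group not in config.groups:
        raise ConfigurationError(f"group {record.group!r} not in config.groups")
    rng = np.random.default_rng(seed)
    n_t = config.n_volumes
    grid = config.grid_shape
    brain = masks.brain_mask
    n_brain = int(brain.sum())

    # network id per in-brain voxel (-1 = non-grey padding)
    net_id = np.full(grid, -1, dtype=int)
    for i, (name, m) in enumerate(masks.named().items()):
        net_id[m] = i
    net_names = list(masks.named().keys())
    vox_net = net_id[brain]

    data = np.zeros((n_brain, n_t))
    bands = config.generation_bands()
    rho = config.network_coherence
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError("network_coherence must lie in [0, 1)")
    for bname, band in bands.items():
        base = band_limited_series(rng, n_brain, n_t, config.tr_s, band)
        if rho > 0:
            # parcels fluctuate coherently: each network shares a common
            # band process carrying fraction rho of the variance
            shared = band_limited_series(
                rng, len(net_names), n_t, config.tr_s, band
            )
            in_net = vox_net >= 0
            base[in_net] = (
                np.sqrt(1.0 - rho) * base[in_net]
                + np.sqrt(rho) * shared[vox_net[in_net]]
            )
        sd = np.full(n_brain, config.band_power[bname])
        for i, net in enumerate(net_names):
            sel = vox_net == i
            factor = config.effect_table.get((record.group, net, bname), 1.0)
            if net == "dmn_posterior" and bname == "slow4":
                # the cognition-linked latent factor is slow4-specific
                factor *= subject_factor
            if factor != 1.0:
                sd[sel] *= factor
        data += base * sd[:, None]

    # shared global nuisance signal with network-specific coupling; the
    # key (group, "brain") couples into every brain voxel (a genuinely
    # global signal), network keys add on top of it
    if config.gs_coupling:
        g = band_limited_series(rng, 1, n_t, config.tr_s, config.gs_band)[0]
        w = np.full(n_brain, config.gs_coupling.get((record.group, "brain"), 0.0))
        for i, net in enumerate(net_names):
            w[vox_net == i] += config.gs_coupling.get((record.group, net), 0.0)
        data += w[:, None] * g

    if config.drift_amp > 0:
        t_norm = np.linspace(-0.5, 0.5, n_t)
        slopes = rng.normal(0.0, config.drift_amp, size=n_brain)
        data += slopes[:, None] * t_norm

    spike_times = np.array([], dtype=int)
    if config.motion_spike_rate > 0:
        n_spikes = rng.poisson(config.motion_spike_rate)
        if n_spikes > 0:
            spike_times = rng.choice(n_t, size=min(n_spikes, n_t), replace=False)
            signs = rng.choice([-1.0, 1.0], size=(n_brain, len(spike_times)))
            data[:, spike_times] += config.spike_amp * signs

    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=(n_brain, n_t))
    data += config.baseline

    vol = np.zeros(grid + (n_t,))
    vol[brain] = data

    motion = np.cumsum(rng.normal(0.0, 0.01, size=(n_t, 6)), axis=0)
    for st in spike_times:
        motion[st:, :3] += rng.normal(0.0, 0.3, size=3)
    csf = rng.normal(0.0, 1.0, size=n_t)
    wm = rng.normal(0.0, 1.0, size=n_t)

    return BoldRun(
        data=vol,
        tr_s=config.tr_s,
        brain_mask=brain,
        provenance=[f"simulate(group={record.group}, seed={seed})"],
        nuisance=NuisanceTraces(motion6=motion, csf=csf, wm=wm),
    )


# ---------------------------------------------------------------------------
# Cohort generation

_COGNITION_BASE = {"HC": 0.0, "aMCI": -3.29, "AD": -7.47}
_DECLINE_BASE = {"HC": -0.07, "aMCI": -0.05, "AD": -1.81}
_MOTION_MEAN = {"HC": 1.24, "aMCI": 1.38, "AD": 1.75}
_MOTION_SD = {"HC": 1.15, "aMCI": 1.07, "AD": 1.25}
_CEVD_P = {"HC": 0.0, "aMCI": 52 / 98, "AD": 46 / 96}
_HIPPOCAMPUS_BASE = 3000.0  # mm^3 (bilateral, elderly-range order of magnitude)


def _truncated_normal(rng, mean, sd, lo, n):
    x = rng.normal(mean, sd, size=n)
    while np.any(x < lo):
        bad = x < lo
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def _sample_phenotypes(config: PhantomConfig):
    """Sample the phenotype table (pure function of config; no imaging).

    Returns ``(table, subj_seeds)``: a DataFrame with the fixed phenotype
    schema plus ``dmn_factor`` (each subject's injected posterior-DMN SD
    factor, the latent variable phenotypes are coupled to) and the
    per-subject imaging seeds derived from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects + 1)
    pheno_rng = np.random.default_rng(children[0])
    subj_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children[1:]]

    labels = [g for g in GROUPS for _ in range(config.groups.get(g, 0))]
    n = len(labels)
    group_factor = np.array(
        [config.effect_table.get((g, "dmn_posterior", "slow4"), 1.0) for g in labels]
    )
    jitter = np.exp(pheno_rng.normal(0.0, config.factor_jitter_sd, size=n))
    factors = group_factor * jitter
    factors_c = factors - factors.mean()

    age = _truncated_normal(pheno_rng, 73.0, 6.0, 40.0, n)
    education = _truncated_normal(pheno_rng, 7.0, 5.0, 0.0, n)
    sex = np.where(pheno_rng.random(n) < 0.45, "M", "F")
    gmv = _truncated_normal(pheno_rng, 600.0, 60.0, 300.0, n)
    motion = np.array(
        [
            _truncated_normal(pheno_rng, _MOTION_MEAN[g], _MOTION_SD[g], 0.0, 1)[0]
            for g in labels
        ]
    )
    cevd = np.array(
        ["Y" if pheno_rng.random() < _CEVD_P[g] else "N" for g in labels]
    )

    cog_base = np.array([_COGNITION_BASE[g] for g in labels])
    cognition_baseline = (
        cog_base
        + config.cognition_slope * factors_c
        + pheno_rng.normal(0.0, config.cognition_noise_sd, size=n)
    )
    decline = (
        np.array([_DECLINE_BASE[g] for g in labels])
        + config.decline_slope * factors_c
        + pheno_rng.normal(0.0, config.decline_noise_sd, size=n)
    )
    cognition_year2 = cognition_baseline + decline
    missing = pheno_rng.random(n) < config.missing_year2_frac
    cognition_year2[missing] = np.nan

    hippo = _truncated_normal(
        pheno_rng, 0.0, config.hippocampus_noise_sd, -np.inf, n
    ) + _HIPPOCAMPUS_BASE + config.hippocampus_slope * factors_c
    hippo = np.clip(hippo, 500.0, None)

    records = []
    for i, g in enumerate(labels):
        rec = SubjectRecord(
            subject_id=f"sub-{i + 1:03d}",
            group=g,
            age=float(age[i]),
            sex=str(sex[i]),
            education=float(education[i]),
            gmv=float(gmv[i]),
            max_abs_motion=float(motion[i]),
            cevd=str(cevd[i]),
            cognition_baseline=float(cognition_baseline[i]),
            cognition_year2=float(cognition_year2[i]),
            hippocampal_volume=float(hippo[i]),
        )
        records.append(rec)

    table = pd.DataFrame([dataclasses.asdict(r) for r in records])[PHENO_COLUMNS]
    table["dmn_factor"] = factors
    table["_jitter"] = jitter
    return table, subj_seeds


def iter_cohort(config: PhantomConfig):
    """Memory-lean cohort generator: yields one ``(record_row, run)`` pair
    at a time, deterministically identical to :func:`simulate_cohort`."""
    masks = make_masks(config)
    table, subj_seeds = _sample_phenotypes(config)
    for i, row in table.iterrows():
        rec = SubjectRecord(**{c: row[c] for c in PHENO_COLUMNS})
        yield row, simulate_subject(
            rec, masks, config, subj_seeds[i], subject_factor=float(row["_jitter"])
        )


def simulate_cohort(config: PhantomConfig):
    """Generate the full cohort: one run per subject, the phenotype table
    and the network masks.

    The returned table carries the fixed phenotype schema plus
    ``dmn_factor``, the injected posterior-DMN SD factor per subject.
    """
    masks = make_masks(config)
    table, subj_seeds = _sample_phenotypes(config)
    runs = []
    for i, row in table.iterrows():
        rec = SubjectRecord(**{c: row[c] for c in PHENO_COLUMNS})
        runs.append(
            simulate_subject(
                rec, masks, config, subj_seeds[i], subject_factor=float(row["_jitter"])
            )
        )
    table = table.drop(columns=["_jitter"])
    return runs, table, masks


# ---------------------------------------------------------------------------
# Labelled ICA component fixtures


def make_labeled_components(n_signal: int, n_noise: int, seed: int):
    """Synthetic spatial-ICA component sets with known signal/noise labels.

    Noise archetypes cycle through the five hallmark signatures used for
    manual classification: spike-laden time series, brain-edge rings,
    non-grey-matter localisation, high-frequency/high-power spectra, and
    sparse alternating-sign spatial maps.  Signal components are smooth,
    band-limited and network-localised.
    """
    from scipy.ndimage import binary_erosion, gaussian_filter

    from .preprocess import ICAComponentSet

    if n_signal < 0 or n_noise < 0:
        raise ValueError("component counts must be non-negative")
    cfg = PhantomConfig()
    masks = make_masks(cfg)
    rng = np.random.default_rng(seed)
    n_t, tr = cfg.n_volumes, cfg.tr_s
    brain = masks.brain_mask
    grey = masks.grey_mask
    edge = brain & ~binary_erosion(brain)
    nongrey = brain & ~grey
    nets = list(masks.named().values())
    nyq = 0.5 / tr

    maps, tcs, labels = [], [], []
    for i in range(n_signal):
        if i % 5 == 4:
            # brain-wide low-frequency component (global/physiological
            # signal, conservatively labelled signal as in manual ratings)
            m = np.zeros(cfg.grid_shape)
            m[brain] = 1.0 + 0.5 * rng.normal(size=int(brain.sum()))
            m = gaussian_filter(m, sigma=1.0) * brain
            tc = band_limited_series(rng, 1, n_t, tr, FrequencyBand("lf", 0.01, 0.08))[0]
        else:
            net = nets[i % len(nets)]
            m = gaussian_filter(net.astype(float), sigma=1.2)
            m *= brain
            band = SLOW4 if i % 2 == 0 else SLOW5
            tc = band_limited_series(rng, 1, n_t, tr, band)[0]
        maps.append(m)
        tcs.append(tc)
        labels.append("signal")

    for j in range(n_noise):
        kind = j % 5
        m = np.zeros(cfg.grid_shape)
        tc = rng.normal(0.0, 0.3, size=n_t)
        if kind == 0:  # motion spikes + edge pattern
            m[edge] = rng.normal(0.0, 1.0, size=int(edge.sum()))
            idx = rng.choice(n_t, size=3, replace=False)
            tc[idx] += rng.choice([-8.0, 8.0], size=3)
        elif kind == 1:  # edge ring with drifting time course
            m[edge] = np.abs(rng.normal(1.0, 0.3, size=int(edge.sum())))
            tc = np.cumsum(rng.normal(0.0, 0.15, size=n_t))
        elif kind == 2:  # non-grey (CSF/WM-like) localisation
            m[nongrey] = rng.normal(0.0, 1.0, size=int(nongrey.sum()))
            m = gaussian_filter(m, sigma=0.8) * brain
            tc += band_limited_series(rng, 1, n_t, tr, FrequencyBand("hf", 0.11, nyq + 1))[0]
        elif kind == 3:  # high frequency, high power
            m[brain] = rng.normal(0.0, 1.0, size=int(brain.sum()))
            m = gaussian_filter(m, sigma=1.0) * brain
            tc = 2.0 * band_limited_series(rng, 1, n_t, tr, FrequencyBand("hf", 0.12, nyq + 1))[0]
        else:  # sparse alternating-sign map
            flat = np.zeros(int(brain.sum()))
            k = max(5, int(0.03 * flat.size))
            idx = rng.choice(flat.size, size=k, replace=False)
            flat[idx] = rng.choice([-3.0, 3.0], size=k)
            m[brain] = flat
            tc += band_limited_series(rng, 1, n_t, tr, SLOW5)[0] * 0.5
        maps.append(m)
        tcs.append(tc)
        labels.append("noise")

    comp = ICAComponentSet(
        spatial_maps=np.array(maps) if maps else np.zeros((0,) + cfg.grid_shape),
        timecourses=np.array(tcs) if tcs else np.zeros((0, n_t)),
        mean_map=np.zeros(cfg.grid_shape),
        brain_mask=brain,
        tr_s=tr,
        labels=list(labels),
    )
    return comp, list(labels)
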