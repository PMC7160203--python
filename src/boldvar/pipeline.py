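"""End-to-end orchestration of the two-arm variability analysis.

``run_pipeline`` executes simulate -> preprocess (GSR and/or ICA arm) ->
per-band z-fSD -> voxelwise group statistics with permutation cluster
inference -> cluster ROI associations -> cohort table, writing every stage
product plus a manifest of hashed outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SLOW4, SLOW5, BoldRun, FrequencyBand, NetworkMasks
from .association import run_association_suite
from .cohortstats import build_table1
from .groupstats import (
    GLMDesign,
    extract_roi_means,
    label_clusters,
    lenient_clusters,
    permutation_cluster_fwe,
)
from .io import write_mask, write_nifti, write_pheno_tsv
from .preprocess import (
    NuisanceSet,
    decompose_ica,
    despike,
    detrend,
    drop_initial_volumes,
    grand_mean_scale,
    motion_exclude,
    regress_nuisance,
    remove_components,
    score_components,
    select_fix_threshold,
    smooth_gaussian,
)
from .synthdata import PhantomConfig, make_labeled_components, make_masks, iter_cohort
from .variability import compute_zfsd

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "preprocess_gsr",
    "preprocess_ica",
    "train_fix_threshold",
    "ConfigError",
]

BANDS = {"slow4": SLOW4, "slow5": SLOW5}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML-loadable)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    arm: str = "gsr"  # gsr | ica | both
    bands: tuple = ("slow4", "slow5")
    n_perm: int = 500
    voxel_p: float = 0.001
    connectivity: int = 18
    drop_volumes: int = 0  # synthetic runs are generated post-settling
    despike_z: float = 4.0
    grand_mean_target: float = 10000.0
    smooth_fwhm_mm: float = 6.0
    motion_threshold_mm: float = 4.0
    fix_train_signal: int = 10
    fix_train_noise: int = 10
    lenient_min_k: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("gsr", "ica", "both"):
            raise ConfigError(f"arm must be gsr|ica|both, got {self.arm!r} (key: arm)")
        for b in self.bands:
            if b not in BANDS:
                raise ConfigError(f"unknown band {b!r} (key: bands)")

    @property
    def arms(self) -> tuple:
        return ("gsr", "ica") if self.arm == "both" else (self.arm,)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        ph = raw.pop("phantom", {})
        if not isinstance(ph, dict):
            raise ConfigError("config key 'phantom' must be a mapping")
        known = {f.name for f in dataclasses.fields(PhantomConfig)}
        bad = set(ph) - known
        if bad:
            raise ConfigError(f"unknown phantom keys: {sorted(bad)}")
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        if "groups" in ph:
            ph["groups"] = dict(ph["groups"])
        if "effect_table" in ph:
            ph["effect_table"] = {
                tuple(k.split("/")): float(v) for k, v in ph["effect_table"].items()
            }
        if "gs_coupling" in ph:
            ph["gs_coupling"] = {
                tuple(k.split("/")): float(v) for k, v in ph["gs_coupling"].items()
            }
        known_top = {f.name for f in dataclasses.fields(cls)} - {"phantom"}
        bad = set(raw) - known_top
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        return cls(phantom=PhantomConfig(**ph), **raw)

    def config_hash(self) -> str:
        def keyed(obj):
            if isinstance(obj, dict):
                return {
                    "/".join(k) if isinstance(k, tuple) else str(k): keyed(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [keyed(v) for v in obj]
            return obj

        blob = json.dumps(
            keyed(dataclasses.asdict(self)), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    arms: tuple
    bands: tuple
    version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Per-subject preprocessing arms


def _nuisance_set(run: BoldRun) -> NuisanceSet:
    tr = run.nuisance
    if tr is None:
        raise ValueError("run carries no nuisance traces")
    return NuisanceSet(motion6=tr.motion6, csf=tr.csf, wm=tr.wm)


def preprocess_gsr(run: BoldRun, cfg: PipelineConfig) -> BoldRun:
    """Nuisance-regression arm (includes global-signal regression)."""
    out = run
    if cfg.drop_volumes:
        out = drop_initial_volumes(out, cfg.drop_volumes)
    out = despike(out, cfg.despike_z)
    out = grand_mean_scale(out, cfg.grand_mean_target)
    out = smooth_gaussian(out, cfg.smooth_fwhm_mm)
    out = detrend(out, order=1)
    out = regress_nuisance(out, _nuisance_set(out), include_global=True)
    return out


def train_fix_threshold(cfg: PipelineConfig):
    """Select the component-rejection threshold on a labelled training set.

    The labelled fixtures live on the default phantom grid, mirroring a
    manually classified training subset."""
    comp, labels = make_labeled_components(
        cfg.fix_train_signal, cfg.fix_train_noise, seed=cfg.seed + 7919
    )
    train_masks = make_masks(PhantomConfig())
    scores = score_components(comp, train_masks, comp.tr_s)
    return select_fix_threshold(scores, labels)


def preprocess_ica(
    run: BoldRun,
    masks: NetworkMasks,
    cfg: PipelineConfig,
    threshold: float,
    seed: int = 0,
) -> BoldRun:
    """ICA-denoising arm (no global-signal regression)."""
    out = run
    if cfg.drop_volumes:
        out = drop_initial_volumes(out, cfg.drop_volumes)
    out = smooth_gaussian(out, cfg.smooth_fwhm_mm)
    out = grand_mean_scale(out, cfg.grand_mean_target)
    comp = decompose_ica(out, seed=seed)
    scores = score_components(comp, masks, out.tr_s)
    noise_ids = [i for i, s in enumerate(scores) if s > threshold]
    if len(noise_ids) == comp.n_components:
        noise_ids = noise_ids[:-1]  # never remove everything
    out = remove_components(out, comp, noise_ids)
    out = detrend(out, order=1)
    return out


# ---------------------------------------------------------------------------
# Full pipeline


def _cluster_table(clusters, band, contrast) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": f"{band}_{contrast}_{i}",
                "band": band,
                "contrast": contrast,
                "size_k": c.size_k,
                "peak_stat": c.peak_stat,
                "peak_x": c.peak_xyz[0],
                "peak_y": c.peak_xyz[1],
                "peak_z": c.peak_xyz[2],
                "p_cluster_fwe": c.p_cluster_fwe,
                "dominant_network": c.dominant_network,
                "correction": c.correction,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full analysis and write all products under ``out_dir``.

    ``config`` may be a path to a YAML file, a dict, or a
    :class:`PipelineConfig`.  Subject runs are simulated and preprocessed
    one at a time so memory stays bounded by a single 4D volume plus the
    per-band z-fSD stacks.
    """
    if isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_dict(config)
    else:
        cfg = config
    if seed is not None:
        cfg = dataclasses.replace(
            cfg, seed=seed, phantom=dataclasses.replace(cfg.phantom, seed=seed)
        )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        arms=cfg.arms,
        bands=cfg.bands,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    stage = "simulate"
    try:
        masks = make_masks(cfg.phantom)
        fix = None
        if "ica" in cfg.arms:
            stage = "fix_training"
            fix = train_fix_threshold(cfg)

        stage = "preprocess"
        zfsd_stacks = {
            arm: {b: [] for b in cfg.bands} for arm in cfg.arms
        }
        rows = []
        for row, run in iter_cohort(cfg.phantom):
            rows.append(row)
            for arm in cfg.arms:
                if arm == "gsr":
                    clean = preprocess_gsr(run, cfg)
                else:
                    clean = preprocess_ica(
                        run, masks, cfg, fix.threshold, seed=cfg.seed + len(rows)
                    )
                maps = compute_zfsd(clean, [BANDS[b] for b in cfg.bands])
                for b in cfg.bands:
                    zfsd_stacks[arm][b].append(maps[b].zfsd)
        records = pd.DataFrame(rows).reset_index(drop=True)
        records = records.drop(columns=["_jitter"], errors="ignore")

        stage = "qc"
        included, _, _ = motion_exclude(records, cfg.motion_threshold_mm)
        keep_idx = included.index.to_numpy()

        stage = "write_cohort"
        p = write_pheno_tsv(records, out_dir / "pheno.tsv")
        manifest.add(p)
        label_vol = np.zeros(cfg.phantom.grid_shape, dtype=np.uint8)
        for i, (name, m) in enumerate(masks.named().items(), start=1):
            label_vol[m] = i
        manifest.add(write_nifti(out_dir / "network_labels.nii.gz", label_vol))
        manifest.add(write_mask(out_dir / "brain_mask.nii.gz", masks.brain_mask))

        stage = "groupstats"
        design_records = included.reset_index(drop=True)
        design = GLMDesign.from_records(design_records)
        analysis_mask = None
        table1 = build_table1(design_records)
        table1.to_csv(out_dir / "table1.tsv", sep="\t", index=False)
        manifest.add(out_dir / "table1.tsv")

        for arm in cfg.arms:
            arm_dir = out_dir / arm
            arm_dir.mkdir(exist_ok=True)
            for b in cfg.bands:
                stack4d = np.stack(zfsd_stacks[arm][b], axis=-1)
                manifest.add(
                    write_nifti(arm_dir / f"zfsd_{b}.nii.gz", stack4d, tr_s=0.0)
                )
                maps_sub = np.stack(
                    [zfsd_stacks[arm][b][i] for i in keep_idx], axis=0
                )
                if analysis_mask is None:
                    analysis_mask = np.all(np.isfinite(maps_sub), axis=0)
                stack = np.stack(
                    [m[analysis_mask] for m in maps_sub], axis=0
                )
                contrasts = ["group", ("aMCI", "HC"), ("HC", "aMCI"), ("AD", "HC"), ("HC", "AD")]
                all_tables = []
                roi_cols = {}
                for contrast in contrasts:
                    cname = contrast if isinstance(contrast, str) else f"{contrast[0]}_gt_{contrast[1]}"
                    clusters = permutation_cluster_fwe(
                        stack,
                        design,
                        contrast,
                        analysis_mask,
                        n_perm=cfg.n_perm,
                        voxel_p=cfg.voxel_p,
                        seed=cfg.seed,
                        connectivity=cfg.connectivity,
                    )
                    sig = [c for c in clusters if c.p_cluster_fwe <= 0.05]
                    label_clusters(sig, masks)
                    all_tables.append(_cluster_table(sig, b, cname))
                    for i, c in enumerate(sig):
                        roi_cols[f"{b}_{cname}_{i}"] = extract_roi_means(maps_sub, c)
                ctab = (
                    pd.concat(all_tables, ignore_index=True)
                    if all_tables
                    else pd.DataFrame()
                )
                ctab.to_csv(arm_dir / f"clusters_{b}.tsv", sep="\t", index=False)
                manifest.add(arm_dir / f"clusters_{b}.tsv")

                stage = "association"
                if roi_cols:
                    roi_df = pd.DataFrame(roi_cols)
                    assoc = run_association_suite(roi_df, design_records, band=b)
                    assoc.to_csv(arm_dir / f"associations_{b}.tsv", sep="\t", index=False)
                    manifest.add(arm_dir / f"associations_{b}.tsv")
                stage = "groupstats"
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    return manifest
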