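"""Voxelwise group comparison of z-fSD maps with cluster-level inference.

Each voxel's z-fSD is modelled by an ordinary least-squares ANCOVA with
diagnostic group (HC/aMCI/AD, dummy-coded against HC) and nuisance
covariates (age, sex, education, total grey-matter volume, optionally
motion and CeVD status).  The omnibus group effect is a 2-df F test;
pairwise group differences are directional t contrasts.

Cluster-level family-wise error is controlled by a Freedman-Lane
permutation scheme: data are residualised on the nuisance covariates, the
residual rows are permuted, and the maximum supra-threshold cluster size
is recorded per permutation to build the null distribution.  A lenient
uncorrected rule (cluster p < 0.05 with extent k >= 40) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import GROUPS, NetworkMasks

__all__ = [
    "GLMDesign",
    "GLMMaps",
    "ClusterResult",
    "fit_voxelwise_glm",
    "form_clusters",
    "permutation_cluster_fwe",
    "lenient_clusters",
    "label_clusters",
    "extract_roi_means",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "gmv")


def _encode(records: pd.DataFrame, col: str) -> np.ndarray:
    x = records[col]
    if col == "sex":
        return (x == "M").to_numpy(dtype=float)
    if col == "cevd":
        return (x == "Y").to_numpy(dtype=float)
    return x.to_numpy(dtype=float)


@dataclass
class GLMDesign:
    """Design matrix for the voxelwise ANCOVA."""

    X: np.ndarray
    columns: list
    group_cols: list  # indices of the group dummy columns
    groups: np.ndarray  # group label per row
    reference: str = "HC"

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        covariates=DEFAULT_COVARIATES,
        reference: str = "HC",
    ) -> "GLMDesign":
        groups = records["group"].to_numpy()
        levels = [g for g in GROUPS if g in set(groups)]
        if reference not in levels:
            reference = levels[0]
        dummies = [g for g in levels if g != reference]
        cols = [np.ones(len(records))]
        names = ["intercept"]
        for g in dummies:
            cols.append((groups == g).astype(float))
            names.append(f"group[{g}]")
        for c in covariates:
            cols.append(_encode(records, c))
            names.append(c)
        X = np.column_stack(cols)
        design = cls(
            X=X,
            columns=names,
            group_cols=list(range(1, 1 + len(dummies))),
            groups=groups,
            reference=reference,
        )
        design.validate()
        return design

    def validate(self) -> None:
        n, p = self.X.shape
        if n <= p + 2:
            raise ValueError(f"too few subjects (n={n}) for {p} design columns")
        rank = np.linalg.matrix_rank(self.X)
        if rank < p:
            c = np.corrcoef(self.X[:, 1:].T)
            bad = [
                (self.columns[i + 1], self.columns[j + 1])
                for i in range(c.shape[0])
                for j in range(i + 1, c.shape[0])
                if abs(c[i, j]) > 1 - 1e-10
            ]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    def contrast_vector(self, pair: tuple) -> np.ndarray:
        """c such that c @ beta estimates mean(a) - mean(b), adjusted."""
        a, b = pair
        c = np.zeros(self.X.shape[1])

        def load(g, sign):
            if g == self.reference:
                return
            name = f"group[{g}]"
            if name not in self.columns:
                raise ValueError(f"group {g!r} absent from design")
            c[self.columns.index(name)] += sign

        load(a, +1.0)
        load(b, -1.0)
        if not np.any(c):
            raise ValueError(f"degenerate contrast {pair}")
        return c

    @property
    def reduced_X(self) -> np.ndarray:
        """Design without the group dummies (the Freedman-Lane null model)."""
        keep = [i for i in range(self.X.shape[1]) if i not in self.group_cols]
        return self.X[:, keep]


@dataclass
class GLMMaps:
    """Flat (in-mask) statistic maps from the voxelwise ANCOVA."""

    F: np.ndarray
    df1: int
    df2: int
    t: dict  # (a, b) -> t map, both orders
    df_t: int
    columns: list


def _rss_floor(Y: np.ndarray) -> np.ndarray:
    """Numerical floor below which a voxel's residual variance is treated
    as exactly zero (degenerate, e.g. constant outcome)."""
    scale = np.einsum("ij,ij->j", Y, Y)
    return 1e-24 * (scale + 1.0)


def _fit_stats(Y: np.ndarray, design: GLMDesign, pairs) -> GLMMaps:
    X = design.X
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    df2 = n - p
    ok = rss > _rss_floor(Y)
    sigma2 = np.where(ok, rss, 1.0) / df2

    Xr = design.reduced_X
    pinv_r = np.linalg.pinv(Xr)
    resid_r = Y - Xr @ (pinv_r @ Y)
    rss_r = np.einsum("ij,ij->j", resid_r, resid_r)
    q = len(design.group_cols)
    F = np.where(ok, (rss_r - rss) / q / sigma2, 0.0)

    xtx_inv = pinv @ pinv.T
    tmaps = {}
    for pair in pairs:
        c = design.contrast_vector(pair)
        denom = float(c @ xtx_inv @ c)
        t = np.where(ok, (c @ beta) / np.sqrt(sigma2 * denom), 0.0)
        tmaps[pair] = t
    return GLMMaps(F=F, df1=q, df2=df2, t=tmaps, df_t=df2, columns=design.columns)


def fit_voxelwise_glm(
    zfsd_stack: np.ndarray, design: GLMDesign, pairs: list | None = None
) -> GLMMaps:
    """OLS ANCOVA at every voxel of a subjects x voxels stack.

    Returns the omnibus group F map and adjusted pairwise t maps for every
    ordered pair of groups present (or the requested ``pairs``).
    """
    if zfsd_stack.shape[0] != design.X.shape[0]:
        raise ValueError("stack rows must match design rows")
    if pairs is None:
        levels = [g for g in GROUPS if g in set(design.groups)]
        pairs = [(a, b) for a in levels for b in levels if a != b]
    return _fit_stats(np.asarray(zfsd_stack, dtype=float), design, pairs)


# ---------------------------------------------------------------------------
# Clusters


@dataclass
class ClusterResult:
    """A supra-threshold cluster."""

    voxels: np.ndarray  # (k, 3) integer coordinates
    size_k: int
    peak_stat: float
    peak_xyz: tuple
    p_cluster_fwe: float | None = None
    network_overlap: dict = field(default_factory=dict)
    dominant_network: str | None = None
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.size_k != len(self.voxels) or self.size_k < 1:
            raise ValueError("size_k must equal the number of voxels (>= 1)")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def _threshold_from_p(voxel_p, kind, df, df1):
    if kind == "t":
        return stats.t.isf(voxel_p, df)
    if kind == "F":
        if df1 is None:
            raise ValueError("df1 required for F maps")
        return stats.f.isf(voxel_p, df1, df)
    raise ValueError(f"unknown statistic kind {kind!r}")


def _clusters_from_supra(stat_vol, supra, structure):
    labels, n = ndimage.label(supra, structure=structure)
    out = []
    for i in range(1, n + 1):
        coords = np.argwhere(labels == i)
        vals = stat_vol[tuple(coords.T)]
        j = int(np.argmax(vals))
        out.append(
            ClusterResult(
                voxels=coords,
                size_k=len(coords),
                peak_stat=float(vals[j]),
                peak_xyz=tuple(int(v) for v in coords[j]),
            )
        )
    out.sort(key=lambda c: (-c.size_k, -c.peak_stat, c.peak_xyz))
    return out


def form_clusters(
    stat_map: np.ndarray,
    df: int,
    voxel_p: float = 0.001,
    connectivity: int = 18,
    kind: str = "t",
    df1: int | None = None,
    mask: np.ndarray | None = None,
) -> list:
    """Group supra-threshold voxels of a 3D statistic map into clusters.

    The voxel-defining threshold is the upper ``voxel_p`` tail of the t
    (one-sided, per contrast direction) or F distribution with the given
    degrees of freedom.  Clusters are deterministic: 18-connectivity by
    default, ordered by size then peak statistic.
    """
    thr = _threshold_from_p(voxel_p, kind, df, df1)
    vol = np.nan_to_num(np.asarray(stat_map, dtype=float), nan=-np.inf)
    supra = vol > thr
    if mask is not None:
        supra &= mask
    return _clusters_from_supra(vol, supra, _structure(connectivity))


def lenient_clusters(
    stat_map: np.ndarray,
    df: int,
    voxel_p: float = 0.001,
    min_k: int = 40,
    connectivity: int = 18,
    kind: str = "t",
    df1: int | None = None,
    mask: np.ndarray | None = None,
) -> list:
    """Uncorrected fallback rule: clusters of extent >= ``min_k`` (inclusive)."""
    out = [
        c
        for c in form_clusters(stat_map, df, voxel_p, connectivity, kind, df1, mask)
        if c.size_k >= min_k
    ]
    for c in out:
        c.correction = "uncorrected_k%d" % min_k
    return out


def permutation_cluster_fwe(
    zfsd_stack: np.ndarray,
    design: GLMDesign,
    contrast,
    mask: np.ndarray,
    n_perm: int = 1000,
    voxel_p: float = 0.001,
    seed: int = 0,
    connectivity: int = 18,
    return_null: bool = False,
):
    """Cluster-level FWE-corrected inference by Freedman-Lane permutation.

    ``contrast`` is "group" for the omnibus F test or an ordered pair
    (a, b) for the one-sided t contrast a > b.  The statistic under
    permutation depends only on the covariate-residualised data, which are
    row-permuted to build the null distribution of the maximum cluster
    size.  Cluster p-values use the (1 + b) / (1 + n_perm) convention.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    Y = np.asarray(zfsd_stack, dtype=float)
    n, V = Y.shape
    if mask.sum() != V:
        raise ValueError("mask voxel count must match stack columns")
    structure = _structure(connectivity)

    X = design.X
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    xtx_inv = pinv @ pinv.T
    df2 = n - p
    q = len(design.group_cols)

    Xr = design.reduced_X
    Hr = Xr @ np.linalg.pinv(Xr)
    R = Y - Hr @ Y  # covariate-residualised data

    if contrast == "group":
        kind, df1 = "F", q
        pinv_r = np.linalg.pinv(Xr)

        def stat(M):
            beta = pinv @ M
            resid = M - X @ beta
            rss = np.einsum("ij,ij->j", resid, resid)
            resid_r = M - Xr @ (pinv_r @ M)
            rss_r = np.einsum("ij,ij->j", resid_r, resid_r)
            ok = rss > _rss_floor(M)
            return np.where(ok, (rss_r - rss) / q * df2 / np.where(ok, rss, 1.0), 0.0)

    else:
        kind, df1 = "t", None
        c = design.contrast_vector(tuple(contrast))
        denom = float(c @ xtx_inv @ c)

        def stat(M):
            beta = pinv @ M
            resid = M - X @ beta
            rss = np.einsum("ij,ij->j", resid, resid)
            ok = rss > _rss_floor(M)
            return np.where(
                ok, (c @ beta) / np.sqrt(np.where(ok, rss, 1.0) / df2 * denom), 0.0
            )

    thr = _threshold_from_p(voxel_p, kind, df2, df1)

    def max_cluster_stat(stat_flat):
        """(size, excess mass) of the largest cluster; mass breaks size ties.

        Cluster size is discrete and, with spatially coherent data, heavily
        tied across permutations; ranking ties by the cluster's excess mass
        (sum of statistic above threshold) keeps the null distribution
        effectively continuous and the p-values calibrated.
        """
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = stat_flat > thr
        if not supra.any():
            return 0, 0.0
        labels, nlab = ndimage.label(supra, structure=structure)
        vol = np.zeros(mask.shape)
        vol[mask] = stat_flat - thr
        sizes = np.bincount(labels.ravel())[1:]
        masses = ndimage.sum_labels(vol, labels, index=np.arange(1, nlab + 1))
        k = int(sizes.max())
        best_mass = float(masses[sizes == k].max())
        return k, best_mass

    # observed clusters
    obs_flat = stat(Y)
    obs_vol = np.full(mask.shape, -np.inf)
    obs_vol[mask] = obs_flat
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = obs_flat > thr
    clusters = _clusters_from_supra(obs_vol, supra, structure)

    excess_vol = np.zeros(mask.shape)
    excess_vol[mask] = obs_flat - thr
    for cl in clusters:
        cl_mass = float(excess_vol[tuple(cl.voxels.T)].sum())
        cl._mass = cl_mass

    rng = np.random.default_rng(seed)
    null_k = np.empty(n_perm, dtype=int)
    null_m = np.empty(n_perm, dtype=float)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null_k[b], null_m[b] = max_cluster_stat(stat(R[perm]))

    for cl in clusters:
        exceed = int(
            ((null_k > cl.size_k) | ((null_k == cl.size_k) & (null_m >= cl._mass))).sum()
        )
        cl.p_cluster_fwe = (1 + exceed) / (1 + n_perm)
        cl.correction = "cluster_fwe_perm"
    if return_null:
        return clusters, null_k
    return clusters


# ---------------------------------------------------------------------------
# Cluster utilities


def label_clusters(clusters: list, masks: NetworkMasks) -> list:
    """Attach per-network overlap fraction and Dice to each cluster."""
    named = masks.named()
    for cl in clusters:
        in_cluster = np.zeros(masks.brain_mask.shape, dtype=bool)
        in_cluster[tuple(cl.voxels.T)] = True
        overlap = {}
        for name, m in named.items():
            inter = int((in_cluster & m).sum())
            frac = inter / cl.size_k
            dice = 2 * inter / (cl.size_k + int(m.sum()))
            overlap[name] = {"fraction": frac, "dice": dice}
        cl.network_overlap = overlap
        best = max(overlap.values(), key=lambda d: d["fraction"])["fraction"]
        winners = [k for k, v in overlap.items() if v["fraction"] == best]
        cl.dominant_network = winners[0] if best > 0 and len(winners) == 1 else "unassigned"
    return clusters


def extract_roi_means(zfsd_maps: np.ndarray, cluster: ClusterResult) -> np.ndarray:
    """Mean z-fSD over the cluster's voxels, per subject.

    ``zfsd_maps`` has shape (n_subjects, x, y, z).
    """
    if cluster.size_k == 0:
        raise ValueError("empty cluster")
    vals = zfsd_maps[(slice(None),) + tuple(cluster.voxels.T)]
    return vals.mean(axis=1)
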