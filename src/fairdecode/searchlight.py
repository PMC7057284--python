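"""Whole-brain classification searchlight and group permutation inference.

A sphere of fixed voxel radius is centered on every in-mask voxel; within
each sphere a linear SVM decodes game type under 6-fold cross-validation
(all sphere voxels enter the classifier -- no top-k step at this scale),
yielding one accuracy map per subject.  Across subjects, each voxel's
accuracy is partially correlated with the UG-DG offer gap (cohort
controlled); significance comes from an empirical null built by shuffling
the behavior across subjects, and surviving voxels are reported as
connected clusters above a minimum size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .decode import DecodeConfig, make_folds
from .glm import TrialPatterns
from .volumes import MaskVolume, connected_components, gaussian_smooth

__all__ = [
    "AccuracyMap",
    "GroupStatMap",
    "smooth_trial_patterns",
    "run_searchlight",
    "SearchLight",
    "voxelwise_behavior_correlation",
    "permutation_null",
    "report_clusters",
]


@dataclass
class AccuracyMap:
    """One subject's voxelwise decoding accuracy (NaN outside the mask)."""

    data: np.ndarray
    mask: np.ndarray
    subject_id: str = "sub-00"
    condition: str = "social"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.shape != self.mask.shape or self.data.ndim != 3:
            raise ValueError("accuracy map and mask grids must match (3-D)")
        inside = self.data[self.mask]
        if inside.size and (np.nanmin(inside) < 0 or np.nanmax(inside) > 1):
            raise ValueError("accuracies must lie in [0, 1] inside the mask")


@dataclass
class GroupStatMap:
    """Group-level partial-correlation map with empirical permutation p-values."""

    r_map: np.ndarray
    p_map: np.ndarray
    mask: np.ndarray
    n_permutations: int
    seed: int
    two_sided: bool = False
    null_max_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        inside_p = self.p_map[self.mask]
        lo = 1.0 / (self.n_permutations + 1)
        if inside_p.size and (inside_p.min() < lo - 1e-12 or inside_p.max() > 1 + 1e-12):
            raise ValueError("empirical p-values must lie in [1/(n_perm+1), 1]")


def smooth_trial_patterns(
    patterns: TrialPatterns,
    fwhm_mm: float = 8.0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TrialPatterns:
    """Spatially smooth each trial's t-map (done before the searchlight so
    its output is more clustered).  Off-pattern voxels are treated as 0."""
    vols = patterns.to_volumes()
    ix = tuple(patterns.voxel_coords.T)
    smoothed = np.empty_like(patterns.values)
    for t in range(patterns.n_trials):
        smoothed[t] = gaussian_smooth(vols[..., t], fwhm_mm, voxel_size_mm)[ix]
    return TrialPatterns(smoothed, patterns.labels, patterns.voxel_coords,
                         patterns.grid_shape, patterns.subject_id,
                         patterns.cohort, patterns.affine)


def run_searchlight(
    patterns: TrialPatterns,
    brain_mask: MaskVolume,
    radius_voxels: float = 3.0,
    config: DecodeConfig | None = None,
    condition_pair: tuple[str, str] = ("UG", "DG"),
    condition: str = "social",
) -> AccuracyMap:
    """Decode game type in a sphere around every in-mask voxel.

    All voxels of the sphere enter the classifier (feature selection is the
    sphere itself); the map value at the center is the 6-fold
    cross-validated accuracy.  Patterns are expected pre-smoothed via
    :func:`smooth_trial_patterns`.
    """
    config = config or DecodeConfig()
    from .volumes import sphere_offsets

    if radius_voxels < 1:
        warnings.warn("searchlight radius < 1 voxel: spheres are single voxels",
                      RuntimeWarning, stacklevel=2)
    keep = patterns.labels["game"].isin(condition_pair).to_numpy()
    y = patterns.labels.loc[keep, "game"].to_numpy()
    if len(set(y)) < 2:
        raise ValueError(f"both conditions of {condition_pair} must be present")
    x_all = np.ascontiguousarray(patterns.values[keep])
    folds = make_folds(y, config.n_folds, seed=config.seed,
                       scheme=config.fold_scheme)
    fold_masks = [(folds == f, folds != f) for f in range(config.n_folds)]
    sizes = np.array([int(t.sum()) for t, _ in fold_masks], dtype=float)

    lut = patterns.column_lookup()
    if brain_mask.data.shape != patterns.grid_shape:
        raise ValueError("brain mask grid does not match the pattern grid")
    if np.any(lut[brain_mask.data] < 0):
        raise ValueError("brain mask reaches voxels not covered by the patterns")
    offsets = sphere_offsets(radius_voxels)
    shape = np.asarray(patterns.grid_shape)
    centers = np.argwhere(brain_mask.data)
    per_pattern = config.scaling == "per_pattern"

    out = np.full(patterns.grid_shape, np.nan)
    for center in centers:
        pts = center[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
        pts = pts[ok]
        pts = pts[brain_mask.data[pts[:, 0], pts[:, 1], pts[:, 2]]]
        cols = lut[pts[:, 0], pts[:, 1], pts[:, 2]]
        x = x_all[:, cols]
        correct = 0.0
        for test, train in fold_masks:
            xt = x[train]
            if per_pattern:
                def z(m):
                    sd = m.std(axis=1, keepdims=True)
                    return (m - m.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)
                xtr, xte = z(xt), z(x[test])
            else:
                mu = xt.mean(axis=0)
                sd = xt.std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                xtr, xte = (xt - mu) / sd, (x[test] - mu) / sd
            svm = SVC(kernel="linear", C=config.svm_cost)
            svm.fit(xtr, y[train])
            correct += float(np.sum(svm.predict(xte) == y[test]))
        out[tuple(center)] = correct / sizes.sum()
    return AccuracyMap(out, brain_mask.data, subject_id=patterns.subject_id,
                       condition=condition, affine=patterns.affine)


class SearchLight:
    """Estimator-style searchlight: configure once, :meth:`fit` per subject.

    ``accuracy_map_`` holds the resulting :class:`AccuracyMap`.
    """

    def __init__(self, radius_voxels: float = 3.0,
                 config: DecodeConfig | None = None,
                 smooth_fwhm_mm: float | None = 8.0,
                 voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)):
        self.radius_voxels = radius_voxels
        self.config = config
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.voxel_size_mm = voxel_size_mm

    def get_params(self, deep: bool = True) -> dict:
        return {"radius_voxels": self.radius_voxels, "config": self.config,
                "smooth_fwhm_mm": self.smooth_fwhm_mm,
                "voxel_size_mm": self.voxel_size_mm}

    def set_params(self, **params) -> "SearchLight":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, patterns: TrialPatterns, brain_mask: MaskVolume,
            condition: str = "social") -> "SearchLight":
        if self.smooth_fwhm_mm:
            patterns = smooth_trial_patterns(patterns, self.smooth_fwhm_mm,
                                             self.voxel_size_mm)
        self.accuracy_map_ = run_searchlight(
            patterns, brain_mask, self.radius_voxels, self.config,
            condition=condition)
        return self


def _stack_maps(maps: list[AccuracyMap]) -> tuple[np.ndarray, np.ndarray]:
    """Common in-mask accuracy matrix (subjects x voxels) and the mask."""
    if len(maps) < 2:
        raise ValueError("need accuracy maps from several subjects")
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all accuracy maps must share one grid and mask")
    acc = np.stack([m.data[mask] for m in maps], axis=0)
    return acc, mask


def _behavior_vectors(
    maps: list[AccuracyMap], behavior: pd.DataFrame,
    diff_column: str, cohort_column: str,
) -> tuple[np.ndarray, np.ndarray]:
    beh = behavior.set_index("subject_id") if "subject_id" in behavior.columns \
        else behavior
    ids = [m.subject_id for m in maps]
    missing = sorted(set(ids) - set(beh.index))
    if missing:
        raise ValueError(f"subjects missing from the behavior table: {missing}")
    rows = beh.loc[ids]
    y = rows[diff_column].to_numpy(dtype=float)
    cohort = (rows[cohort_column].to_numpy() == np.max(rows[cohort_column])).astype(float)
    return y, cohort


def _partial_r_columns(acc: np.ndarray, y: np.ndarray, cohort: np.ndarray) -> np.ndarray:
    """Vectorized partial correlation of each accuracy column with y,
    controlling for [1, cohort].  Degenerate columns give NaN."""
    n = acc.shape[0]
    z = np.column_stack([np.ones(n), cohort])
    q, _ = np.linalg.qr(z)
    racc = acc - q @ (q.T @ acc)
    ry = y - q @ (q.T @ y)
    sy = np.linalg.norm(ry)
    sacc = np.linalg.norm(racc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (racc.T @ ry) / (sacc * sy)
    scale = max(sy, 1.0)
    r[sacc <= 1e-12 * max(scale, 1.0)] = np.nan
    if sy <= 1e-12:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)


def voxelwise_behavior_correlation(
    maps: list[AccuracyMap],
    behavior: pd.DataFrame,
    diff_column: str = "ug_dg_diff_human",
    cohort_column: str = "cohort",
) -> np.ndarray:
    """Per-voxel partial correlation (cohort-controlled) between subject
    accuracy maps and the UG-DG offer gap.  Returns a 3-D r map with NaN
    outside the mask and at degenerate voxels."""
    acc, mask = _stack_maps(maps)
    if acc.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    y, cohort = _behavior_vectors(maps, behavior, diff_column, cohort_column)
    r = _partial_r_columns(acc, y, cohort)
    out = np.full(mask.shape, np.nan)
    out[mask] = r
    return out


def permutation_null(
    maps: list[AccuracyMap],
    behavior: pd.DataFrame,
    n_permutations: int = 500,
    seed: int = 0,
    diff_column: str = "ug_dg_diff_human",
    cohort_column: str = "cohort",
    two_sided: bool = False,
    shuffle_cohort_jointly: bool = True,
    exhaustive: bool = False,
) -> GroupStatMap:
    """Empirical voxelwise p-values from shuffled-behavior null maps.

    Each permutation reassigns the behavior rows across subjects (by default
    jointly with their cohort label, preserving the behavior-cohort
    relationship) and recomputes the partial-correlation map.  The one-sided
    p at a voxel is (1 + #{perm: r_perm >= r_obs}) / (1 + n_permutations);
    the two-sided variant compares |r|.  With ``exhaustive=True`` all n!
    distinct reassignments are enumerated instead (small cohorts only) and
    p = #{perm: r_perm >= r_obs} / n!, which includes the identity.
    """
    acc, mask = _stack_maps(maps)
    y, cohort = _behavior_vectors(maps, behavior, diff_column, cohort_column)
    r_obs = _partial_r_columns(acc, y, cohort)
    n = len(y)
    if exhaustive:
        import itertools
        import math

        if n > 8:
            raise ValueError("exhaustive enumeration only for n <= 8 subjects")
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
        n_permutations = math.factorial(n)
    else:
        if n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_permutations)]
    exceed = np.zeros(acc.shape[1])
    valid = np.isfinite(r_obs)
    obs = np.abs(r_obs) if two_sided else r_obs
    null_max = np.empty(len(perms))
    for b, perm in enumerate(perms):
        cz = cohort[perm] if shuffle_cohort_jointly else cohort
        r_null = _partial_r_columns(acc, y[perm], cz)
        stat = np.abs(r_null) if two_sided else r_null
        exceed[valid] += (stat[valid] >= obs[valid] - 1e-12)
        null_max[b] = np.nanmax(stat) if np.any(np.isfinite(stat)) else np.nan
    if exhaustive:
        p = exceed / n_permutations
    else:
        p = (1.0 + exceed) / (1.0 + n_permutations)
    p[~valid] = 1.0
    r_vol = np.full(mask.shape, np.nan)
    p_vol = np.ones(mask.shape)
    r_vol[mask] = r_obs
    p_vol[mask] = p
    p_vol[~mask] = 1.0
    return GroupStatMap(r_vol, p_vol, mask, n_permutations, seed,
                        two_sided=two_sided, null_max_r=null_max)


def report_clusters(
    stat: GroupStatMap,
    alpha: float = 0.005,
    min_size: int = 15,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Cluster table of suprathreshold voxels (p < alpha, size > min_size).

    Columns: cluster_id, size, peak_r, peak_x/y/z.
    """
    supra = (stat.p_map < alpha) & stat.mask
    clusters = connected_components(
        MaskVolume(supra, name="suprathreshold"), connectivity=connectivity,
        values=np.nan_to_num(stat.r_map, nan=-np.inf))
    rows = []
    for label in range(1, len(clusters) + 1):
        size = int(clusters.sizes[label - 1])
        if size <= min_size:
            continue
        peak = clusters.peaks[label - 1]
        rows.append({"cluster_id": len(rows) + 1, "size": size,
                     "peak_r": float(stat.r_map[tuple(peak)]),
                     "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                     "peak_z": int(peak[2])})
    return pd.DataFrame(rows, columns=["cluster_id", "size", "peak_r",
                                       "peak_x", "peak_y", "peak_z"])
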