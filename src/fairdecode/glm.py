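"""Single-trial GLM pattern estimation (least-squares-all).

Every trial receives its own regressor in one joint model: a 6-s boxcar
ending at the subject's keypress, convolved with a canonical double-gamma
hemodynamic response function and sampled at the volume acquisition times.
Nuisance series (average background signal, white-matter signal) and an
intercept are appended.  Both the data and the task regressors pass through
the same Gaussian high-pass filter before the fit, so drift removal does not
bias the trial estimates.  Per-trial betas are converted to t-values, the
pattern currency of all downstream decoding.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import FWHM_TO_SIGMA, MaskVolume

__all__ = [
    "BoldRun",
    "DesignMatrix",
    "TrialPatterns",
    "GlmFit",
    "validate_events",
    "double_gamma_hrf",
    "build_lsa_design",
    "gaussian_highpass",
    "fit_glm",
    "betas_to_t",
    "nuisance_regressors",
    "estimate_trial_patterns",
    "LsaGlm",
    "EPOCH_S",
    "OFFER_GRID",
]

#: decision epoch: seconds counted back from the keypress
EPOCH_S = 6.0
#: admissible offers in euros
OFFER_GRID = tuple(range(0, 15, 2))

GAMES = ("UG", "DG")
OPPONENTS = ("human", "computer")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-trial event table.

    Required columns: onset, duration, game, opponent, response_time, offer.
    Onsets must be strictly increasing, the keypress cannot precede trial
    onset and offers must lie on the 0..14 euro grid in steps of 2.
    """
    required = ["onset", "duration", "game", "opponent", "response_time", "offer"]
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    ev = events.reset_index(drop=True)
    onsets = ev["onset"].to_numpy(dtype=float)
    if len(ev) and np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    if np.any(ev["response_time"].to_numpy(dtype=float) < onsets):
        raise ValueError("response_time must be at or after trial onset")
    bad_game = set(ev["game"]) - set(GAMES)
    if bad_game:
        raise ValueError(f"unknown game labels: {sorted(bad_game)}")
    bad_opp = set(ev["opponent"]) - set(OPPONENTS)
    if bad_opp:
        raise ValueError(f"unknown opponent labels: {sorted(bad_opp)}")
    offers = ev["offer"].to_numpy(dtype=float)
    if not np.all(np.isin(offers, OFFER_GRID)):
        raise ValueError(f"offers must lie on the grid {OFFER_GRID}")
    return ev


@dataclass
class BoldRun:
    """A preprocessed 4-D BOLD run on a regular grid.

    ``data`` is (x, y, z, volume); ``tr_s`` the repetition time in seconds;
    ``brain_mask`` a boolean 3-D array on the same grid.
    """

    data: np.ndarray
    tr_s: float
    brain_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask grid does not match data grid")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s


@dataclass
class DesignMatrix:
    """volumes x regressors design with named columns.

    ``trial_columns`` indexes the single-trial regressors; the remaining
    columns are nuisance series plus the intercept.
    """

    matrix: np.ndarray
    column_names: list[str]
    trial_columns: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match matrix")
        self.trial_columns = np.asarray(self.trial_columns, dtype=int)

    @property
    def n_trials(self) -> int:
        return len(self.trial_columns)


@dataclass
class TrialPatterns:
    """Per-trial activation patterns: a trials x voxels matrix of t-values.

    ``labels`` carries one row per trial with at least ``game`` and
    ``opponent``; ``voxel_coords`` maps columns back to 3-D voxel indices on
    ``grid_shape``.
    """

    values: np.ndarray
    labels: pd.DataFrame
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    subject_id: str = "sub-00"
    cohort: int = 1
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("pattern values must be trials x voxels")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must have one row per trial")
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        if self.voxel_coords.shape != (self.values.shape[1], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def column_lookup(self) -> np.ndarray:
        """3-D volume mapping voxel index -> column (-1 outside coverage)."""
        lut = np.full(self.grid_shape, -1, dtype=int)
        lut[tuple(self.voxel_coords.T)] = np.arange(self.n_voxels)
        return lut

    def select_trials(self, keep: np.ndarray) -> "TrialPatterns":
        keep = np.asarray(keep)
        return TrialPatterns(self.values[keep], self.labels.iloc[keep],
                             self.voxel_coords, self.grid_shape,
                             self.subject_id, self.cohort, self.affine)

    def to_volumes(self) -> np.ndarray:
        """Render patterns as a 4-D array, one volume per trial (NaN-free: 0 outside)."""
        vols = np.zeros(self.grid_shape + (self.n_trials,), dtype=float)
        ix = tuple(self.voxel_coords.T)
        for t in range(self.n_trials):
            vols[ix + (t,)] = self.values[t]
        return vols


def double_gamma_hrf(
    dt_s: float,
    length_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_dispersion_s: float = 1.0,
    undershoot_dispersion_s: float = 1.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, sampled every ``dt_s``.

    The kernel is the difference of two gamma densities -- a positive lobe
    peaking near ``peak_delay_s`` minus an undershoot near
    ``undershoot_delay_s`` scaled by ``1 / undershoot_ratio`` -- rescaled to
    unit peak.  The defaults are the conventional canonical parameterization
    (delay 6 s, undershoot delay 16 s, ratio 6).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if length_s < 24.0:
        raise ValueError("kernel length must cover at least 24 s")
    t = np.arange(0.0, length_s + dt_s / 2, dt_s)
    peak = stats.gamma.pdf(t, peak_delay_s / peak_dispersion_s,
                           scale=peak_dispersion_s)
    undershoot = stats.gamma.pdf(t, undershoot_delay_s / undershoot_dispersion_s,
                                 scale=undershoot_dispersion_s)
    h = peak - undershoot / undershoot_ratio
    return h / h.max()


def _trial_regressors(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    epoch_s: float,
    hrf_dt_s: float,
    hrf_kwargs: dict | None,
) -> np.ndarray:
    """HRF-convolved epoch boxcars sampled at volume times, (n_volumes, n_trials)."""
    run_end = n_volumes * tr_s
    hrf = double_gamma_hrf(hrf_dt_s, **(hrf_kwargs or {}))
    n_fine = int(np.ceil(run_end / hrf_dt_s)) + 1
    fine_t = np.arange(n_fine) * hrf_dt_s
    vol_idx = np.rint(np.arange(n_volumes) * tr_s / hrf_dt_s).astype(int)
    cols = np.zeros((n_volumes, len(events)))
    for i, trial in events.iterrows():
        rt = float(trial["response_time"])
        # keypress anchors the epoch; truncate at trial onset for fast responses
        start = max(float(trial["onset"]), rt - epoch_s)
        if start < 0:
            raise ValueError(
                f"trial {i}: epoch [{start:.1f}, {rt:.1f}] s extends "
                "before the run start")
        if rt > run_end:
            raise ValueError(
                f"trial {i}: keypress at {rt:.1f} s falls after the run end "
                f"({run_end:.1f} s)")
        boxcar = ((fine_t >= start) & (fine_t < rt)).astype(float)
        # dt factor approximates the continuous convolution integral
        conv = np.convolve(boxcar, hrf)[:n_fine] * hrf_dt_s
        cols[:, i] = conv[vol_idx]
    return cols


def build_lsa_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float,
    nuisance: dict[str, np.ndarray] | None = None,
    epoch_s: float = EPOCH_S,
    hrf_dt_s: float = 0.1,
    hrf_kwargs: dict | None = None,
) -> DesignMatrix:
    """Build the least-squares-all design: one regressor per trial.

    Each trial contributes a boxcar over the ``epoch_s`` seconds preceding
    its keypress, convolved with the double-gamma HRF.  Nuisance series and
    an intercept are appended after the trial columns.  The returned design
    must be full column rank; offending columns are named otherwise.
    """
    events = validate_events(events)
    trial_block = _trial_regressors(events, n_volumes, tr_s, epoch_s,
                                    hrf_dt_s, hrf_kwargs)
    names = [f"trial_{i:03d}" for i in range(len(events))]
    blocks = [trial_block]
    for nname, series in (nuisance or {}).items():
        series = np.asarray(series, dtype=float).ravel()
        if series.shape != (n_volumes,):
            raise ValueError(f"nuisance '{nname}' must have {n_volumes} samples")
        blocks.append(series[:, None])
        names.append(nname)
    blocks.append(np.ones((n_volumes, 1)))
    names.append("intercept")
    matrix = np.hstack(blocks)
    design = DesignMatrix(matrix, names, np.arange(len(events)))
    _check_full_rank(design)
    return design


def _check_full_rank(design: DesignMatrix) -> None:
    x = design.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via rank-revealing QR pivots
        _, r, piv = _qr_pivot(x)
        bad = sorted(design.column_names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def gaussian_highpass(
    series: np.ndarray,
    cutoff_fwhm_s: float = 100.0,
    tr_s: float = 2.0,
) -> np.ndarray:
    """Gaussian-weighted running-line high-pass filter.

    Each timepoint's low-frequency component is the value at that point of a
    straight line fitted by Gaussian-weighted least squares (sigma =
    FWHM / (2 sqrt(2 ln 2)) converted to volumes), the semantics of the
    Gaussian high-pass in standard fMRI preprocessing tools.  The filtered
    series is the residual with the original mean restored.

    ``series`` may be 1-D (time) or 2-D (time x channels).
    """
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    y = series[:, None] if one_d else series
    n = y.shape[0]
    if n < 3:
        raise ValueError("series must have at least 3 samples")
    if cutoff_fwhm_s <= 2 * tr_s:
        raise ValueError("cutoff FWHM must exceed twice the TR")
    smoother = _running_line_smoother(n, cutoff_fwhm_s * FWHM_TO_SIGMA / tr_s)
    out = y - smoother @ y
    out += y.mean(axis=0, keepdims=True) - out.mean(axis=0, keepdims=True)
    return out[:, 0] if one_d else out


def _running_line_smoother(n: int, sigma_vol: float) -> np.ndarray:
    """Linear operator of the Gaussian-weighted local line fit (n x n)."""
    half = max(1, int(np.ceil(4 * sigma_vol)))
    smoother = np.zeros((n, n))
    t = np.arange(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = t[lo:hi] - i
        w = np.exp(-0.5 * (x / sigma_vol) ** 2)
        sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
        det = sw * swx2 - swx**2
        # fitted value at the window center: intercept of the weighted line
        smoother[i, lo:hi] = (swx2 * w - swx * w * x) / det
    return smoother


@dataclass
class GlmFit:
    """OLS fit of one design against all in-mask voxel time series."""

    betas: np.ndarray           # (n_regressors, n_voxels)
    residual_variance: np.ndarray  # (n_voxels,)
    design: DesignMatrix
    voxel_coords: np.ndarray    # (n_voxels, 3)
    grid_shape: tuple[int, int, int]
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def fit_glm(bold: BoldRun, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per voxel inside the brain mask.

    Returns betas and the residual variance RSS / (n - p) per voxel.
    """
    x = design.matrix
    if x.shape[0] != bold.n_volumes:
        raise ValueError(
            f"design has {x.shape[0]} rows but the run has {bold.n_volumes} volumes")
    _check_full_rank(design)
    coords = np.argwhere(bold.brain_mask)
    y = bold.data[bold.brain_mask].T.astype(float)  # (n_volumes, n_voxels)
    betas, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ betas
    dof = x.shape[0] - x.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    return GlmFit(betas, sigma2, design, coords, bold.data.shape[:3],
                  bold.tr_s, bold.affine)


def betas_to_t(
    fit: GlmFit,
    events: pd.DataFrame,
    subject_id: str = "sub-00",
    cohort: int = 1,
    t_cap: float = 1e6,
) -> TrialPatterns:
    """Convert per-trial betas to t-values: t_i = b_i / (s * sqrt([(X'X)^-1]_ii)).

    Non-trial columns are dropped; condition labels are attached from the
    event table.  Voxels with zero residual variance would give infinite t;
    these are capped at ``t_cap`` with a warning.
    """
    events = validate_events(events)
    design = fit.design
    if len(events) != design.n_trials:
        raise ValueError("event table and design disagree on the trial count")
    x = design.matrix
    xtx_inv = np.linalg.inv(x.T @ x)
    var_scale = np.diag(xtx_inv)[design.trial_columns]  # (n_trials,)
    se = np.sqrt(fit.residual_variance[None, :] * var_scale[:, None])
    b = fit.betas[design.trial_columns]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    t = np.where(se == 0, np.sign(b) * t_cap, t)
    capped = ~np.isfinite(t) | (np.abs(t) > t_cap)
    if np.any(capped):
        warnings.warn("zero residual variance at some voxels; t capped",
                      RuntimeWarning, stacklevel=2)
        t = np.nan_to_num(t, nan=0.0, posinf=t_cap, neginf=-t_cap)
    t = np.clip(t, -t_cap, t_cap)
    labels = events[["game", "opponent", "response_time", "offer"]].copy()
    return TrialPatterns(t, labels, fit.voxel_coords, fit.grid_shape,
                         subject_id=subject_id, cohort=cohort, affine=fit.affine)


def nuisance_regressors(
    bold: BoldRun,
    wm_mask: MaskVolume | np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Average background and white-matter signals as regressors of no interest.

    Background is the mean time course over voxels outside the brain mask
    (omitted when the mask fills the grid); white matter is the mean over the
    supplied mask.  Both are demeaned.
    """
    out: dict[str, np.ndarray] = {}
    background = ~bold.brain_mask
    if background.any():
        series = bold.data[background].mean(axis=0)
        out["background"] = series - series.mean()
    if wm_mask is not None:
        wm = wm_mask.data if isinstance(wm_mask, MaskVolume) else np.asarray(wm_mask, bool)
        if not wm.any():
            raise ValueError("white-matter mask is empty")
        series = bold.data[wm].mean(axis=0)
        out["white_matter"] = series - series.mean()
    return out


def estimate_trial_patterns(
    bold: BoldRun,
    events: pd.DataFrame,
    wm_mask: MaskVolume | np.ndarray | None = None,
    highpass_fwhm_s: float | None = 100.0,
    epoch_s: float = EPOCH_S,
    subject_id: str = "sub-00",
    cohort: int = 1,
    hrf_kwargs: dict | None = None,
) -> TrialPatterns:
    """Full single-subject pattern estimation: design, filter, fit, t-convert.

    The high-pass filter (default 100 s FWHM) is applied to the voxel time
    series and to the trial and nuisance regressors alike, leaving the
    intercept untouched, so that filtering cannot bias the trial estimates.
    """
    events = validate_events(events)
    nuisance = nuisance_regressors(bold, wm_mask)
    design = build_lsa_design(events, bold.n_volumes, bold.tr_s,
                              nuisance=nuisance, epoch_s=epoch_s,
                              hrf_kwargs=hrf_kwargs)
    data = bold.data
    if highpass_fwhm_s is not None:
        y = data[bold.brain_mask].T.astype(float)
        y = gaussian_highpass(y, highpass_fwhm_s, bold.tr_s)
        data = np.array(data, dtype=float, copy=True)
        data[bold.brain_mask] = y.T
        filt_cols = [j for j, name in enumerate(design.column_names)
                     if name != "intercept"]
        mat = design.matrix.copy()
        mat[:, filt_cols] = gaussian_highpass(mat[:, filt_cols],
                                              highpass_fwhm_s, bold.tr_s)
        design = DesignMatrix(mat, design.column_names, design.trial_columns)
    run = BoldRun(data, bold.tr_s, bold.brain_mask, bold.affine)
    fit = fit_glm(run, design)
    return betas_to_t(fit, events, subject_id=subject_id, cohort=cohort)


class LsaGlm:
    """Estimator-style wrapper around the single-trial GLM.

    Follows the scikit-learn convention: configure in ``__init__``, call
    :meth:`fit` with the run and event table, read ``patterns_`` afterwards.
    """

    def __init__(self, highpass_fwhm_s: float | None = 100.0,
                 epoch_s: float = EPOCH_S, hrf_kwargs: dict | None = None):
        self.highpass_fwhm_s = highpass_fwhm_s
        self.epoch_s = epoch_s
        self.hrf_kwargs = hrf_kwargs

    def get_params(self, deep: bool = True) -> dict:
        return {"highpass_fwhm_s": self.highpass_fwhm_s,
                "epoch_s": self.epoch_s, "hrf_kwargs": self.hrf_kwargs}

    def set_params(self, **params) -> "LsaGlm":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, bold: BoldRun, events: pd.DataFrame,
            wm_mask: MaskVolume | np.ndarray | None = None,
            subject_id: str = "sub-00", cohort: int = 1) -> "LsaGlm":
        self.patterns_ = estimate_trial_patterns(
            bold, events, wm_mask=wm_mask,
            highpass_fwhm_s=self.highpass_fwhm_s, epoch_s=self.epoch_s,
            subject_id=subject_id, cohort=cohort, hrf_kwargs=self.hrf_kwargs)
        return self

    def transform(self, bold: BoldRun = None, events: pd.DataFrame = None) -> TrialPatterns:
        if not hasattr(self, "patterns_"):
            raise AttributeError("LsaGlm is not fitted yet")
        return self.patterns_
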