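"""Relating per-subject decoding accuracy to behavior.

The central statistic is the partial Pearson correlation between a
subject-level brain measure (decoding accuracy) and the behavioral
selfishness index (mean UG minus DG offer), controlling for a cohort dummy
that absorbs the scanner/sample difference between the two study samples.
Multiple ROIs within a network are corrected with Benjamini-Hochberg FDR;
social vs non-social correlations are compared after Fisher z transform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decode import DecodingResult

__all__ = [
    "CorrelationResult",
    "partial_correlation",
    "fdr_adjust",
    "fisher_z_compare",
    "accuracy_behavior_table",
]


@dataclass
class CorrelationResult:
    """A (partial) correlation with its two-sided p-value.

    ``degenerate`` flags a residual with (near-)zero variance, where the
    correlation is undefined; r is reported as 0 and p as NaN in that case.
    """

    r: float
    p: float
    n: int
    n_covariates: int = 0
    roi_name: str = ""
    condition: str = ""
    degenerate: bool = False
    p_adjusted: float | None = None

    @property
    def df(self) -> int:
        return self.n - 2 - self.n_covariates


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residual of v after least-squares projection onto [1, z]."""
    design = np.column_stack([np.ones(len(v))] + ([z] if z.size else []))
    coef, _, _, _ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    roi_name: str = "",
    condition: str = "",
) -> CorrelationResult:
    """Pearson correlation of x and y after removing covariates from both.

    Both variables are residualized on an intercept plus the covariate
    columns; the correlation of the residuals is tested with
    t = r sqrt(df) / sqrt(1 - r^2), df = n - 2 - n_covariates, two-sided.
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("x and y must be finite (no missing values)")
    if covariates is None:
        z = np.empty((len(x), 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    n, k = len(x), z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} observations, got {n}")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    sx, sy = np.sqrt((rx**2).sum()), np.sqrt((ry**2).sum())
    scale = max(float(np.linalg.norm(x - x.mean())),
                float(np.linalg.norm(y - y.mean())), 1.0)
    if sx <= 1e-12 * scale or sy <= 1e-12 * scale:
        return CorrelationResult(0.0, np.nan, n, k, roi_name, condition,
                                 degenerate=True)
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r, p, n, k, roi_name, condition)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations after Fisher z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.  Requires |r| < 1 and n > 3 in both samples.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("each sample must have more than 3 subjects")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def accuracy_behavior_table(
    results: list[DecodingResult],
    behavior: pd.DataFrame,
    diff_column: str = "ug_dg_diff_human",
    cohort_column: str = "cohort",
    fdr_families: dict[str, list[str]] | None = None,
) -> list[CorrelationResult]:
    """Partial correlation of decoding accuracy with the UG-DG offer gap.

    One correlation per (ROI, condition) cell, always controlling for the
    cohort dummy.  ``fdr_families`` maps a family name to the ROI names it
    contains (e.g. all clusters of one network mask); BH adjustment is
    applied within each family and condition.  ROIs not assigned to any
    family form one residual family per condition.
    """
    behavior = behavior.set_index("subject_id") if "subject_id" in behavior.columns \
        else behavior
    table = pd.DataFrame(
        {"subject_id": [r.subject_id for r in results],
         "roi_name": [r.roi_name for r in results],
         "condition": [r.condition for r in results],
         "accuracy": [r.accuracy for r in results]})
    missing = sorted(set(table["subject_id"]) - set(behavior.index))
    if missing:
        raise ValueError(f"subjects missing from the behavior table: {missing}")

    out: list[CorrelationResult] = []
    for (roi, condition), grp in table.groupby(["roi_name", "condition"], sort=True):
        grp = grp.sort_values("subject_id")
        beh = behavior.loc[grp["subject_id"]]
        cohort_dummy = (beh[cohort_column].to_numpy() ==
                        np.max(beh[cohort_column])).astype(float)
        res = partial_correlation(
            grp["accuracy"].to_numpy(), beh[diff_column].to_numpy(),
            covariates=cohort_dummy, roi_name=roi, condition=condition)
        out.append(res)

    # BH within each (family, condition)
    families = dict(fdr_families or {})
    assigned = {roi for members in families.values() for roi in members}
    rest = sorted({r.roi_name for r in out} - assigned)
    if rest:
        families["_unassigned"] = rest
    for condition in sorted({r.condition for r in out}):
        for members in families.values():
            cell = [r for r in out
                    if r.condition == condition and r.roi_name in members
                    and not r.degenerate]
            if not cell:
                continue
            adj = fdr_adjust([r.p for r in cell])
            for r, a in zip(cell, adj):
                r.p_adjusted = float(a)
    return out
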