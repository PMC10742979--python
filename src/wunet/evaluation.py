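"""Cohort-level comparison of metric recovery across denoising models.

For each of the six stack-level metabolic summaries, the Pearson
correlation between values derived from a model's denoised stacks and from
ground-truth stacks is computed across the cohort.  Correlations are
compared between models with the Fisher r-to-z transform,

    z_r = (1/2) * ln((1 + r) / (1 - r)),

whose sampling distribution is approximately normal with variance
1/(n - 3), giving the two-sample test statistic

    Z = (z_r1 - z_r2) / sqrt(1/(n1 - 3) + 1/(n2 - 3))

with a two-tailed normal p-value.  Because figures in this field report
both r and the coefficient of determination, records carry r and r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metabolic import SUMMARY_NAMES, MetricProfile, stack_metrics
from .stack_io import TissueStack

__all__ = ["CorrelationRecord", "pearson_r", "fisher_z", "z_test",
           "significance_stars", "cohort_metrics", "cohort_report"]

#: correlations of +/-1 are clipped to this before the z transform
_R_CLIP = 1.0 - 1e-12


@dataclass
class CorrelationRecord:
    metric_name: str
    model_name: str
    r: float
    n: int
    z: float

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("n must be >= 4 for the z-test variance")
        if abs(self.r) > 1:
            raise ValueError("|r| cannot exceed 1")


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN pairs are dropped.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def fisher_z(r: float) -> float:
    """Variance-stabilising transform z_r = arctanh(r); odd and strictly
    increasing on (-1, 1)."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return float(np.arctanh(r))


def z_test(r1: float, n1: int, r2: float, n2: int
           ) -> tuple[float, float]:
    """Two-sample comparison of correlations via Fisher z.

    Returns (Z, two-tailed p).  Correlations of exactly +/-1 are clipped
    just inside the open interval so perfect-recovery cohorts remain
    reportable.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3")
    r1 = float(np.clip(r1, -_R_CLIP, _R_CLIP))
    r2 = float(np.clip(r2, -_R_CLIP, _R_CLIP))
    z = (fisher_z(r1) - fisher_z(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# cohort machinery
# ---------------------------------------------------------------------------

def cohort_metrics(stacks: dict[str, tuple[TissueStack, TissueStack]],
                   masks: dict[str, np.ndarray] | None = None,
                   fit_range=None) -> pd.DataFrame:
    """Six summary metrics per ROI for a cohort keyed by roi_id.

    ``stacks`` maps roi_id -> (nadph_stack, fad_stack).
    """
    rows = []
    for roi_id, (nadph, fad) in stacks.items():
        mp = stack_metrics(nadph, fad,
                           masks=None if masks is None else masks[roi_id],
                           fit_range=fit_range)
        rows.append({"roi_id": roi_id, **mp.summaries})
    return pd.DataFrame(rows).set_index("roi_id")


def cohort_report(models: dict[str, pd.DataFrame], gt: pd.DataFrame,
                  raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation table and pairwise z-tests for a cohort.

    ``models`` maps model name to a per-ROI summary table as produced by
    :func:`cohort_metrics`; ``gt`` and ``raw`` are the ground-truth and
    single-frame tables.  All tables must be indexed by the same roi_ids.

    Returns (records, comparisons): one row per (metric, model) with r,
    r^2, n and z; and one row per (metric, model pair) with the Z
    statistic, p-value and significance stars.
    """
    all_models = {"RAW": raw, **models}
    for name, tab in all_models.items():
        if not tab.index.equals(gt.index):
            if set(tab.index) != set(gt.index):
                raise ValueError(f"cohort {name!r} is not aligned with "
                                 "ground truth")
            all_models[name] = tab.loc[gt.index]
    rec_rows, cmp_rows = [], []
    r_table: dict[tuple[str, str], tuple[float, int]] = {}
    for metric in SUMMARY_NAMES:
        for name, tab in all_models.items():
            x = tab[metric].to_numpy()
            y = gt[metric].to_numpy()
            keep = np.isfinite(x) & np.isfinite(y)
            n = int(keep.sum())
            if n >= 3:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    r = pearson_r(x[keep], y[keep])
            else:
                r = float("nan")
            z = (fisher_z(float(np.clip(r, -_R_CLIP, _R_CLIP)))
                 if np.isfinite(r) else float("nan"))
            r_table[(metric, name)] = (r, n)
            rec_rows.append({"metric": metric, "model": name, "r": r,
                             "r_squared": r * r, "n": n, "z": z})
        names = list(all_models)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ra, na = r_table[(metric, a)]
                rb, nb = r_table[(metric, b)]
                if not (np.isfinite(ra) and np.isfinite(rb)):
                    continue
                if na <= 3 or nb <= 3:
                    continue   # z-test variance undefined
                Z, p = z_test(ra, na, rb, nb)
                cmp_rows.append({"metric": metric, "model_1": a,
                                 "model_2": b, "Z": Z, "p": p,
                                 "stars": significance_stars(p)})
    return pd.DataFrame(rec_rows), pd.DataFrame(cmp_rows)
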