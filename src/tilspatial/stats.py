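"""Cohort-level feature screening against Miller-Payne grade.

Two screens, adjusted separately for multiple testing because they answer
different questions:

* Spearman rank correlation of each feature with the ordinal MP grade
  (1-5), two-sided p from the t approximation on n-2 degrees of freedom.
* Mann-Whitney U comparison of MP1-3 (low/intermediate response) versus
  MP4-5 (high response), exact p for small untied samples and the
  tie/continuity-corrected normal approximation otherwise.

Both screens apply Benjamini-Hochberg step-up FDR adjustment over the
screen's full tested feature family.  Missing feature values are handled
pairwise-complete, with ``n_used`` reported so power differences stay
visible.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MIN_SPEARMAN_N = 3


class ResponseGroup(str, enum.Enum):
    LOW_INTERMEDIATE = "LOW_INTERMEDIATE"  # MP 1-3
    HIGH = "HIGH"                          # MP 4-5


@dataclass
class CohortMatrix:
    """Samples × named features with per-sample MP grade labels."""

    features: pd.DataFrame
    mp_grade: pd.Series

    def validate(self) -> "CohortMatrix":
        if len(self.features) != len(self.mp_grade):
            raise ValueError("feature rows and grade labels differ in length")
        if not self.features.index.equals(self.mp_grade.index):
            raise ValueError("feature and grade indices do not align")
        if self.features.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        grades = self.mp_grade.to_numpy()
        if not np.isin(grades, [1, 2, 3, 4, 5]).all():
            raise ValueError("MP grades must be integers in 1..5")
        return self

    @property
    def groups(self) -> pd.Series:
        return self.mp_grade.map(lambda g: mp_binarize(g).value)


def mp_binarize(grade: int) -> ResponseGroup:
    """MP 1-3 → low/intermediate response, MP 4-5 → high response."""
    if grade not in (1, 2, 3, 4, 5):
        raise ValueError(f"MP grade must be in 1..5, got {grade!r}")
    return ResponseGroup.HIGH if grade >= 4 else ResponseGroup.LOW_INTERMEDIATE


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j>=i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman_screen(matrix: CohortMatrix) -> pd.DataFrame:
    """Spearman R of every feature vs MP grade, with BH q-values.

    Features with fewer than 3 pairwise-complete samples, or constant
    values, are skipped (logged) and excluded from the BH family.
    """
    matrix.validate()
    grades = matrix.mp_grade.to_numpy(dtype=float)
    rows = []
    for name in matrix.features.columns:
        x = matrix.features[name].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(grades)
        n_used = int(mask.sum())
        if n_used < MIN_SPEARMAN_N:
            logger.info("spearman: skipping %s (only %d complete pairs)", name, n_used)
            continue
        xv, gv = x[mask], grades[mask]
        if np.ptp(xv) == 0 or np.ptp(gv) == 0:
            logger.info("spearman: skipping %s (constant input)", name)
            continue
        res = sps.spearmanr(xv, gv)
        rows.append(
            {"feature": name, "statistic": float(res.statistic),
             "p": float(res.pvalue), "n_used": n_used}
        )
    if not rows:
        logger.warning("spearman screen: no testable features")
        return pd.DataFrame(columns=["feature", "statistic", "p", "q", "n_used"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["feature", "statistic", "p", "q", "n_used"]]


def mannwhitney_screen(matrix: CohortMatrix) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of HIGH vs LOW_INTERMEDIATE per feature.

    U is reported for the HIGH group (so U above its null mean means the
    feature is larger in high responders).  The exact distribution is used
    for combined n ≤ 20 without ties; otherwise the normal approximation
    with tie and continuity correction.
    """
    matrix.validate()
    is_high = (matrix.groups == ResponseGroup.HIGH.value).to_numpy()
    rows = []
    for name in matrix.features.columns:
        x = matrix.features[name].to_numpy(dtype=float)
        mask = np.isfinite(x)
        hi, lo = x[mask & is_high], x[mask & ~is_high]
        if len(hi) == 0 or len(lo) == 0:
            logger.info("mannwhitney: skipping %s (an empty group)", name)
            continue
        n = len(hi) + len(lo)
        has_ties = len(np.unique(np.concatenate([hi, lo]))) < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
        rows.append(
            {"feature": name, "statistic": float(res.statistic),
             "p": float(res.pvalue), "n_used": n}
        )
    if not rows:
        logger.warning("mannwhitney screen: no testable features")
        return pd.DataFrame(columns=["feature", "statistic", "p", "q", "n_used"])
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["feature", "statistic", "p", "q", "n_used"]]
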