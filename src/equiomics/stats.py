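"""Univariate statistics shared by the expression and metabolite stages.

The differential callers deliberately mirror the asymmetric thresholds of
the two assay types: differentially expressed genes (DEGs) require a
Benjamini-Hochberg adjusted p below 0.05 with fold change >= 2 or <= 0.5
(inclusive), while differentially accumulated metabolites (DAMs) use the
*raw* p below 0.05 with a strict fold change > 2 (two-sided by default,
i.e. also < 0.5).  Helper closed forms (FPKM, the 2^-ddCt relative
expression, ppm mass matching) and the metabolite missing-value filter
live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign

STUDENT_LOG2 = "student_log2"
WELCH_LOG2 = "welch_log2"
STUDENT = "student"


@dataclass
class OmicsMatrix:
    """Features x samples numeric table bound to a study design.

    Columns must be ``line_rep`` sample names resolvable against the
    design.  Missing cells (NaN) are allowed — metabolite matrices use
    them — and are never silently treated as zero.
    """

    data: pd.DataFrame
    design: StudyDesign

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        for col in self.data.columns:
            self.design.line_of(col)  # raises with the offending column name
        self.data = self.data.astype(float)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    def group(self, line: str) -> pd.DataFrame:
        cols = [c for c in self.data.columns if self.design.line_of(c) == line]
        if not cols:
            raise ValueError(f"no samples for line {line!r}")
        return self.data[cols]


@dataclass
class DifferentialRecord:
    feature: str
    comparison: str
    fold_change: float
    log2fc: float
    p_value: float
    p_adjusted: float
    call: bool
    vip: float | None = None
    degenerate: bool = False


def parse_comparison(comparison) -> tuple[str, str]:
    """Accept ``"A/B"`` labels or ``(A, B)`` pairs."""
    if isinstance(comparison, str):
        a, sep, b = comparison.partition("/")
        if not sep or not a or not b:
            raise ValueError(f"comparison label must be 'A/B': {comparison!r}")
        return a, b
    a, b = comparison
    return str(a), str(b)


# ---------------------------------------------------------------------------
# closed forms


def fpkm(count: float, feature_length: float, library_size: float) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length <= 0 or library_size <= 0:
        raise ValueError("feature_length and library_size must be > 0")
    return count * 1e9 / (library_size * feature_length)


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def ppm_match(
    observed_mass: float, theoretical_mass: float, tolerance: float = 25.0
) -> tuple[bool, float]:
    """Accurate-mass match: ppm error strictly below the tolerance."""
    if observed_mass <= 0 or theoretical_mass <= 0:
        raise ValueError("masses must be > 0")
    ppm = abs(observed_mass - theoretical_mass) / theoretical_mass * 1e6
    return ppm < tolerance, ppm


# ---------------------------------------------------------------------------
# tests and adjustment


def group_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    mode: str = WELCH_LOG2,
    pseudocount: float = 1.0,
) -> float:
    """Two-sided two-sample t test between replicate groups.

    ``student_log2`` (the default for the callers) pools variance and
    tests log2(value + pseudocount) — with a handful of replicates per
    group and a common noise model, pooling is the calibrated choice;
    ``welch_log2`` drops the equal-variance assumption at the cost of
    unstable degrees of freedom at n = 3; ``student`` is the classical
    equal-variance t on raw values (the qPCR-verification convention).
    Degenerate inputs — fewer than two
    finite values in a group, or zero variance in both groups — return
    p = 1.0 rather than raising, so callers can keep such features
    flagged-but-uncalled.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return 1.0
    if mode in (WELCH_LOG2, STUDENT_LOG2):
        a, b = np.log2(a + pseudocount), np.log2(b + pseudocount)
        equal_var = mode == STUDENT_LOG2
    elif mode == STUDENT:
        equal_var = True
    else:
        raise ValueError(f"unknown test mode: {mode!r}")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0
    p = sps.ttest_ind(a, b, equal_var=equal_var).pvalue
    return 1.0 if not np.isfinite(p) else float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential calling


def _fold_changes(mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float):
    """Ratio of group means; the pseudocount enters only when a mean is 0."""
    fc = np.empty_like(mean_a)
    zero = (mean_a <= 0) | (mean_b <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc[~zero] = mean_a[~zero] / mean_b[~zero]
        fc[zero] = (mean_a[zero] + pseudocount) / (mean_b[zero] + pseudocount)
    return fc


def _vector_ttest(A: np.ndarray, B: np.ndarray, mode: str, pseudocount: float):
    """Row-wise t test; returns (p, degenerate flag) arrays."""
    if mode in (WELCH_LOG2, STUDENT_LOG2):
        A = np.log2(A + pseudocount)
        B = np.log2(B + pseudocount)
        equal_var = mode == STUDENT_LOG2
    elif mode == STUDENT:
        equal_var = True
    else:
        raise ValueError(f"unknown test mode: {mode!r}")
    n_a = np.sum(np.isfinite(A), axis=1)
    n_b = np.sum(np.isfinite(B), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(A, B, axis=1, equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (n_a < 2) | (n_b < 2) | ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    return p, degenerate


def _differential(
    matrix: OmicsMatrix,
    comparison,
    up,
    down,
    p_threshold: float,
    adjusted: bool,
    inclusive: bool,
    mode: str,
    pseudocount: float | None,
    vip: dict | None = None,
) -> list[DifferentialRecord]:
    line_a, line_b = parse_comparison(comparison)
    label = f"{line_a}/{line_b}"
    A = matrix.group(line_a).to_numpy()
    B = matrix.group(line_b).to_numpy()
    if pseudocount is None:
        positive = matrix.data.to_numpy()
        positive = positive[np.isfinite(positive) & (positive > 0)]
        pseudocount = 0.5 * positive.min() if positive.size else 1.0
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
    mean_a = np.nan_to_num(mean_a)
    mean_b = np.nan_to_num(mean_b)
    fc = _fold_changes(mean_a, mean_b, pseudocount)
    p, degenerate = _vector_ttest(A, B, mode, pseudocount)
    padj = bh_adjust(p)
    p_used = padj if adjusted else p
    if inclusive:
        fc_hit = (fc >= up) | (fc <= down)
    else:
        fc_hit = (fc > up) | (fc < down)
    calls = fc_hit & (p_used < p_threshold) & ~degenerate
    records = []
    for i, feature in enumerate(matrix.features):
        records.append(
            DifferentialRecord(
                feature=feature,
                comparison=label,
                fold_change=float(fc[i]),
                log2fc=float(np.log2(fc[i])) if fc[i] > 0 else float("-inf"),
                p_value=float(p[i]),
                p_adjusted=float(padj[i]),
                call=bool(calls[i]),
                vip=None if vip is None else vip.get(feature),
                degenerate=bool(degenerate[i]),
            )
        )
    return records


def call_degs(
    matrix: OmicsMatrix,
    comparison,
    padj_threshold: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    mode: str = STUDENT_LOG2,
    pseudocount: float = 1.0,
) -> list[DifferentialRecord]:
    """Differentially expressed genes for one pairwise line comparison.

    A gene is called when its BH-adjusted p (over the comparison's full
    feature set) is below ``padj_threshold`` and its fold change is
    >= ``fc_up`` or <= ``fc_down`` (both inclusive).
    """
    return _differential(
        matrix, comparison, fc_up, fc_down, padj_threshold,
        adjusted=True, inclusive=True, mode=mode, pseudocount=pseudocount,
    )


def call_dams(
    matrix: OmicsMatrix,
    comparison,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    two_sided: bool = True,
    mode: str = STUDENT_LOG2,
    vip: dict | None = None,
) -> list[DifferentialRecord]:
    """Differentially accumulated metabolites for one comparison.

    Calls require raw p < ``p_threshold`` and fold change strictly
    > ``fc_threshold`` (or < 1/threshold when ``two_sided``).  VIP values
    from a discriminant model may be attached for reporting; they do not
    enter the call.  Apply :func:`missing_value_filter` first.
    """
    down = 1.0 / fc_threshold if two_sided else 0.0
    return _differential(
        matrix, comparison, fc_threshold, down, p_threshold,
        adjusted=False, inclusive=False, mode=mode, pseudocount=None, vip=vip,
    )


def missing_value_filter(matrix: OmicsMatrix, max_missing: float = 0.5) -> OmicsMatrix:
    """Drop features missing in more than ``max_missing`` (strict) of the
    replicates of *any* line group."""
    drop = pd.Series(False, index=matrix.data.index)
    for line in matrix.design.lines:
        grp = matrix.group(line)
        frac = grp.isna().sum(axis=1) / grp.shape[1]
        drop |= frac > max_missing
    return OmicsMatrix(matrix.data.loc[~drop].copy(), matrix.design)
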