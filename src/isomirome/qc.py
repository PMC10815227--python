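"""Sample quality gates: hemolysis screening and library outlier detection.

Plasma miRNA profiles are easily contaminated by erythrocyte miRNAs released
during blood draw.  The qPCR hemolysis gate compares miR-23a-3p (plasma) to
miR-451a (red-cell): ΔCt = Ct(miR-23a-3p) − Ct(miR-451a) < 7 cycles marks a
non-hemolytic sample (strict inequality).

After sequencing, degenerate libraries are identified from detection rates
and inter-library agreement: for the subsets of features present (raw count
≥ 1) in at least 3 or at least 5 libraries, each library's detection count
within the subset is tallied, and pairwise Spearman correlations are
computed on RPM over all features.  A library is an outlier when its
≥5-subset detection count falls below the lower Tukey fence (Q1 − 1.5·IQR)
or its median correlation with the other libraries drops below 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import rpm_normalize
from .errors import InputError
from .matrix import CountMatrix

HEMOLYSIS_DELTA_CT_MAX = 7.0
MIN_MEDIAN_CORRELATION = 0.6


@dataclass(frozen=True)
class HemolysisResult:
    sample_id: str
    ct_23a: float
    ct_451a: float
    delta_ct: float
    passed: bool


@dataclass(frozen=True)
class LibraryQcReport:
    sample_id: str
    n_detected: int
    n_in_common3: int
    n_in_common5: int
    median_intercorrelation: float
    outlier: bool


def hemolysis_check(ct_23a: float, ct_451a: float, sample_id: str = "") -> HemolysisResult:
    """ΔCt hemolysis gate; passes iff Ct(23a) − Ct(451a) < 7 (strict)."""
    for name, ct in (("ct_23a", ct_23a), ("ct_451a", ct_451a)):
        if not math.isfinite(ct) or ct <= 0:
            raise InputError(f"{name} must be finite and positive, got {ct}")
    delta = ct_23a - ct_451a
    return HemolysisResult(
        sample_id=sample_id,
        ct_23a=float(ct_23a),
        ct_451a=float(ct_451a),
        delta_ct=float(delta),
        passed=delta < HEMOLYSIS_DELTA_CT_MAX,
    )


def detection_subsets(matrix: CountMatrix, k: int) -> set[str]:
    """Features present (raw count ≥ 1) in at least ``k`` libraries."""
    if not 1 <= k <= matrix.n_samples:
        raise InputError(f"k must be in [1, {matrix.n_samples}], got {k}")
    if matrix.normalized:
        raise InputError("detection is defined on raw counts")
    present = (matrix.data.to_numpy() >= 1).sum(axis=1)
    return {f for f, n in zip(matrix.feature_ids, present) if n >= k}


def interlibrary_correlation(matrix: CountMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation between libraries on RPM over all features."""
    if matrix.n_samples < 2:
        raise InputError("need at least 2 libraries")
    rpm = matrix if matrix.normalized else rpm_normalize(matrix)
    rho = stats.spearmanr(rpm.data.to_numpy()).statistic
    if np.isscalar(rho) or np.ndim(rho) == 0:  # spearmanr collapses 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=matrix.sample_ids, columns=matrix.sample_ids)


def library_outlier_scan(
    matrix: CountMatrix, min_correlation: float = MIN_MEDIAN_CORRELATION
) -> list[LibraryQcReport]:
    """Flag degenerate libraries by detection counts and inter-correlation.

    The ≥3/≥5 common-feature subsets are computed once over all libraries
    (the library under test is not excluded from the tally).
    """
    if matrix.n_samples < 4:
        raise InputError("outlier scan needs at least 4 libraries")
    common3 = detection_subsets(matrix, 3)
    common5 = detection_subsets(matrix, 5)
    idx3 = [i for i, f in enumerate(matrix.feature_ids) if f in common3]
    idx5 = [i for i, f in enumerate(matrix.feature_ids) if f in common5]
    present = matrix.data.to_numpy() >= 1
    n_detected = present.sum(axis=0)
    n_in3 = present[idx3].sum(axis=0)
    n_in5 = present[idx5].sum(axis=0)

    corr = interlibrary_correlation(matrix).to_numpy()
    med_corr = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        others = np.delete(corr[j], j)
        med_corr[j] = np.median(others)

    q1, q3 = np.percentile(n_in5, [25, 75])
    fence = q1 - 1.5 * (q3 - q1)

    reports = []
    for j, sid in enumerate(matrix.sample_ids):
        reports.append(
            LibraryQcReport(
                sample_id=sid,
                n_detected=int(n_detected[j]),
                n_in_common3=int(n_in3[j]),
                n_in_common5=int(n_in5[j]),
                median_intercorrelation=float(med_corr[j]),
                outlier=bool(n_in5[j] < fence or med_corr[j] < min_correlation),
            )
        )
    return reports


def qc_report_frame(reports: list[LibraryQcReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports]).set_index("sample_id")
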