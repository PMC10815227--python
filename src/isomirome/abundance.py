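"""RPM normalization, isomiR→miRNA aggregation, and the abundance filter.

Abundance is expressed as reads per million (RPM): each raw count is divided
by its library's total isomiR read count and scaled by 1e6.  The library
total is the matrix's own column sum, computed before any feature filtering,
so retained-feature RPM columns are directly comparable across libraries.

A feature is sufficiently abundant for the correlation screen when its mean
RPM across libraries exceeds 5 and its maximal RPM exceeds 50 (both strict).
The same rule applies unchanged at the isomiR and the aggregated-miRNA
level.  The dynamic range of a feature is the ratio of its highest to lowest
RPM; it is undefined (NaN) when the minimum is zero.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .matrix import CountMatrix

MEAN_RPM_MIN = 5.0
MAX_RPM_MIN = 50.0


def rpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Reads-per-million view of a raw count matrix.

    Raises :class:`InputError` naming the library if any column total is 0.
    """
    if matrix.normalized:
        raise InputError("matrix is already RPM-normalized")
    totals = matrix.library_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise InputError(f"zero-total library: {', '.join(map(str, zero.index))}")
    rpm = matrix.data.div(totals, axis=1) * 1e6
    return CountMatrix(rpm, level=matrix.level, normalized=True)


def aggregate_mirna(isomir_matrix: CountMatrix, parent_of: Mapping[str, str]) -> CountMatrix:
    """Sum isomiR-level raw counts over their parent miRNA.

    Per-library totals are conserved exactly, so RPM computed from the
    aggregate equals the sum of member-isomiR RPMs.
    """
    if isomir_matrix.level != "isomir":
        raise InputError("aggregation expects an isomiR-level matrix")
    if isomir_matrix.normalized:
        raise InputError("aggregate raw counts, not RPM")
    missing = [f for f in isomir_matrix.feature_ids if f not in parent_of]
    if missing:
        raise InputError(f"{len(missing)} features lack a parent assignment")
    parents = pd.Index([parent_of[f] for f in isomir_matrix.feature_ids], name="feature_id")
    agg = isomir_matrix.data.groupby(parents, sort=True).sum()
    return CountMatrix(agg, level="mirna", normalized=False)


def dynamic_range(rpm_values: np.ndarray) -> float:
    """max/min RPM across libraries; NaN when the minimum is zero."""
    v = np.asarray(rpm_values, dtype=float)
    lo, hi = v.min(), v.max()
    if lo <= 0:
        return float("nan")
    return float(hi / lo)


def abundance_filter(
    rpm_matrix: CountMatrix,
    mean_rpm_min: float = MEAN_RPM_MIN,
    max_rpm_min: float = MAX_RPM_MIN,
) -> pd.DataFrame:
    """Per-feature abundance summary and the dual abundance gate.

    Returns one row per feature: mean, SD (n−1 denominator), max, min,
    dynamic range and ``passed_filter`` = (mean > mean_rpm_min) AND
    (max > max_rpm_min), strict on both sides.
    """
    if not rpm_matrix.normalized:
        raise InputError("abundance filter expects an RPM-normalized matrix")
    values = rpm_matrix.data.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(values))
    vmax = values.max(axis=1)
    vmin = values.min(axis=1)
    with np.errstate(divide="ignore"):
        dyn = np.where(vmin > 0, vmax / np.where(vmin > 0, vmin, 1.0), np.nan)
    return pd.DataFrame(
        {
            "feature_id": rpm_matrix.feature_ids,
            "level": rpm_matrix.level,
            "mean_rpm": mean,
            "sd_rpm": sd,
            "max_rpm": vmax,
            "min_rpm": vmin,
            "dynamic_range": dyn,
            "passed_filter": (mean > mean_rpm_min) & (vmax > max_rpm_min),
        }
    ).set_index("feature_id")
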