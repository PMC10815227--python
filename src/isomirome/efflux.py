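"""Cholesterol-efflux (reverse cholesterol transport) quantification.

Radiolabelled cholesterol is loaded into macrophages; ApoB-depleted plasma
from each patient serves as the acceptor.  For every well, total efflux is
the percentage of label recovered in the medium:

    total% = 100 · CPM_medium / (CPM_medium + CPM_lysate)

Each sample is measured in triplicate and every plate carries one no-plasma
blank.  Before averaging, replicates whose total efflux deviates from the
triplicate mean by at least 1.15 sample standard deviations are removed
(single pass, no re-iteration; with three values at most one replicate can
ever be removed).  Specific efflux subtracts the blank's total efflux and
may be slightly negative, which is reported as-is.

Associations between specific efflux and the clinical score (or selected
feature abundances) use Pearson's r — these are percentage-scale assay
values, not count data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

TRIPLICATE_SD_RULE = 1.15

PLATE_COLUMNS = ["sample_id", "replicate_index", "cpm_medium", "cpm_lysate", "is_blank"]


@dataclass
class EffluxSample:
    sample_id: str
    replicates: list[tuple[float, float]]  # (cpm_medium, cpm_lysate)
    cleaned_mask: list[bool] = field(default_factory=list)
    total_efflux_pct: float = float("nan")
    specific_efflux_pct: float = float("nan")
    flagged: bool = False


def total_efflux(cpm_medium: float, cpm_lysate: float) -> float:
    """Percent of label in the medium: 100·m/(m+l)."""
    if cpm_medium < 0 or cpm_lysate < 0:
        raise InputError("CPM readings must be non-negative")
    denom = cpm_medium + cpm_lysate
    if denom == 0:
        raise InputError("medium + lysate CPM is zero")
    return 100.0 * cpm_medium / denom


def specific_efflux(sample_total_pct: float, blank_total_pct: float) -> float:
    """Blank-subtracted efflux; slightly negative values are reported as-is."""
    return sample_total_pct - blank_total_pct


def triplicate_clean(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Apply the 1.15-SD triplicate rule to per-replicate efflux percentages.

    Returns ``(mask, flagged)``: mask is True for retained replicates.  Mean
    and SD (n−1 denominator) are computed once over the three values; every
    value deviating by ≥ 1.15·SD is removed, without re-iteration.  SD = 0
    removes nothing.  If the rule would leave fewer than two values, all are
    retained and the sample is flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (3,):
        raise InputError(f"expected a triplicate, got {v.shape}")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.ones(3, dtype=bool), False
    mask = np.abs(v - v.mean()) < TRIPLICATE_SD_RULE * sd
    if mask.sum() < 2:
        return np.ones(3, dtype=bool), True
    return mask, False


def process_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-sample efflux metrics from a plate table.

    ``plate`` columns: sample_id, replicate_index, cpm_medium, cpm_lysate,
    is_blank (exactly one blank row per plate).  Returns one row per sample
    with replicate totals, the cleaning mask, mean total efflux over
    retained replicates, and blank-subtracted specific efflux.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise InputError(f"plate table missing columns: {missing}")
    blanks = plate[plate["is_blank"].astype(bool)]
    if len(blanks) != 1:
        raise InputError(f"expected exactly one blank well, found {len(blanks)}")
    blank_total = total_efflux(
        float(blanks.iloc[0]["cpm_medium"]), float(blanks.iloc[0]["cpm_lysate"])
    )

    rows = []
    for sid, grp in plate[~plate["is_blank"].astype(bool)].groupby("sample_id", sort=False):
        grp = grp.sort_values("replicate_index")
        totals = np.array(
            [total_efflux(m, l) for m, l in zip(grp["cpm_medium"], grp["cpm_lysate"])]
        )
        if len(totals) == 3:
            mask, flagged = triplicate_clean(totals)
        else:  # tolerate plates with a lost well: keep what was measured
            mask, flagged = np.ones(len(totals), dtype=bool), len(totals) < 2
        mean_total = float(totals[mask].mean())
        rows.append(
            {
                "sample_id": sid,
                "n_replicates": len(totals),
                "n_retained": int(mask.sum()),
                "replicate_totals": ";".join(f"{t:.4f}" for t in totals),
                "total_efflux_pct": mean_total,
                "total_efflux_pct_uncleaned": float(totals.mean()),
                "specific_efflux_pct": specific_efflux(mean_total, blank_total),
                "blank_total_pct": blank_total,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def efflux_associations(
    efflux: pd.DataFrame,
    scores: Mapping[str, float],
    feature_rpms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson correlations of specific efflux with the clinical score and,
    optionally, with each feature's RPM abundance (rows = features, columns
    = samples).  Requires ≥ 4 paired observations per correlation.
    """
    shared = [s for s in efflux.index if s in scores]
    if len(shared) < 4:
        raise InputError(f"only {len(shared)} samples have both efflux and score")
    e = efflux.loc[shared, "specific_efflux_pct"].to_numpy(dtype=float)
    rows = []
    sc = np.array([float(scores[s]) for s in shared])
    r, p = stats.pearsonr(e, sc)
    rows.append({"pair": "specific_efflux~score", "r": float(r), "p_value": float(p), "n": len(shared)})

    if feature_rpms is not None:
        for fid, vals in feature_rpms.iterrows():
            common = [s for s in shared if s in vals.index]
            if len(common) < 4:
                continue
            ev = efflux.loc[common, "specific_efflux_pct"].to_numpy(dtype=float)
            fv = vals[common].to_numpy(dtype=float)
            if np.ptp(fv) == 0 or np.ptp(ev) == 0:
                continue
            r, p = stats.pearsonr(ev, fv)
            rows.append(
                {
                    "pair": f"specific_efflux~{fid}",
                    "r": float(r),
                    "p_value": float(p),
                    "n": len(common),
                }
            )
    return pd.DataFrame(rows, columns=["pair", "r", "p_value", "n"])
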