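"""The correlation screen: Spearman ρ, permutation p-values, BH-FDR,
ROC-AUC discrimination, and isomiR-vs-parent superiority comparison.

The screen tests each feature's RPM abundance against a continuous clinical
score (a 0–99 cardiovascular-risk percentile).  Features with |Spearman ρ|
≥ 0.55 become candidates; significance is assessed by shuffling the score
assignment across patients (10,000 permutations by default) and counting
how often the shuffled |ρ| is at least the observed |ρ|.  "At least as good"
is read on the absolute value because negatively correlated markers are
retained by the screen.  Candidate p-values are Benjamini–Hochberg adjusted
within each level (miRNA and isomiR separately) over the full family of
screened features — the candidate gate pre-selects small p-values, so the
non-candidates enter the correction as p = 1; p-adj < 0.05 is significant.

Discrimination dichotomizes the cohort at the 75th risk percentile (score
≥ 75 = high) and computes the Mann–Whitney AUC with ties counted 1/2,
oriented as "higher abundance predicts high risk" with no automatic flip.
The 95% CI is DeLong's; a marker is discriminative when the lower CI bound
exceeds 0.5.

An isomiR is *superior* to its parent miRNA when it simultaneously shows a
higher |ρ|, a lower adjusted p-value, a larger dynamic range of abundance,
and a higher AUC.  It is an *isomiR-only* finding when it is significant
while its parent's aggregated counts are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .matrix import CountMatrix

RHO_THRESHOLD = 0.55
ALPHA = 0.05
ROC_CUTOFF = 75
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation null of the correlation screen.

    ``add_one_smoothing`` switches the estimator from count/n (the screen's
    default, which can return exactly 0) to (count+1)/(n+1) for users who
    need strictly positive p-values.
    """

    n_perm: int = 10_000
    rng_seed: int = 0
    add_one_smoothing: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise InputError(f"n_perm must be at least 100, got {self.n_perm}")


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    discriminative: bool


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=-1, method="average")


def _standardize_rows(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rank rows; flags constant rows."""
    centered = ranks - ranks.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1, keepdims=True)
    constant = norms[..., 0] == 0
    safe = np.where(norms == 0, 1.0, norms)
    return centered / safe, constant


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with midranks on ties.

    Returns NaN (the undefined marker) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise InputError("need 1-D vectors of length >= 3")
    rx, cx = _standardize_rows(_rank_rows(x))
    ry, cy = _standardize_rows(_rank_rows(y))
    if cx or cy:
        return float("nan")
    return float(rx @ ry)


def score_permutations(n: int, config: PermutationConfig) -> np.ndarray:
    """The shared, seeded stream of score shufflings (n_perm × n indices).

    One stream is reused across every feature of a screen so that the full
    set of p-values is jointly reproducible and preserves the cross-feature
    dependence of the null.
    """
    rng = np.random.default_rng(config.rng_seed)
    return np.array([rng.permutation(n) for _ in range(config.n_perm)])


def permutation_pvalues(
    values: np.ndarray,
    scores: Sequence[float],
    config: PermutationConfig | None = None,
    perms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for each row of ``values`` against ``scores``.

    Returns ``(p_perm, rho_obs)``.  p = #{|ρ_perm| ≥ |ρ_obs|} / n_perm,
    evaluated against one shared permutation stream.
    """
    config = config or PermutationConfig()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if values.shape[1] != len(scores):
        raise InputError("scores length does not match value columns")
    feat, feat_const = _standardize_rows(_rank_rows(values))
    if feat_const.any():
        raise InputError("constant feature has undefined observed rho")
    score_ranks = _rank_rows(scores)
    sc, sc_const = _standardize_rows(score_ranks)
    if sc_const:
        raise InputError("constant score vector has undefined observed rho")
    rho_obs = feat @ sc

    if perms is None:
        perms = score_permutations(len(scores), config)
    counts = np.zeros(len(values), dtype=np.int64)
    threshold = np.abs(rho_obs)[:, None] - _TIE_EPS
    # evaluate in blocks to bound the features × permutations matrix
    for start in range(0, len(perms), 2048):
        block = sc[perms[start : start + 2048]]  # standardized permuted score ranks
        rho_perm = feat @ block.T
        counts += (np.abs(rho_perm) >= threshold).sum(axis=1)
    if config.add_one_smoothing:
        p = (counts + 1) / (config.n_perm + 1)
    else:
        p = counts / config.n_perm
    return p, rho_obs


def permutation_pvalue(
    feature_values: Sequence[float],
    scores: Sequence[float],
    config: PermutationConfig | None = None,
) -> float:
    """Single-feature convenience wrapper around :func:`permutation_pvalues`."""
    p, _ = permutation_pvalues(np.asarray(feature_values)[None, :], scores, config)
    return float(p[0])


def bh_adjust(p_values: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (capped at 1, order preserved).

    ``family_size`` sets the number m of tests in the family when it exceeds
    the number of supplied p-values: the missing members are treated as
    p = 1 (they occupy the top ranks and never lower any adjusted value).
    The screen uses this to correct candidate-gated permutation p-values
    over the full set of screened features — candidates are a selected,
    sub-uniform subset, so correcting over the candidates alone would
    understate the multiplicity.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise InputError(f"family_size {m} smaller than the {len(p)} p-values given")
    order = np.argsort(p, kind="mergesort")
    q = np.empty(len(p))
    running = 1.0
    for rank in range(len(p), 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def stratify_high_low(scores: Sequence[float], cutoff: float = ROC_CUTOFF) -> np.ndarray:
    """High/low risk labels: high ⇔ score ≥ cutoff (the 75th percentile)."""
    scores = np.asarray(scores, dtype=float)
    labels = scores >= cutoff
    if labels.all() or not labels.any():
        raise InputError(
            f"single-class cohort at cutoff {cutoff}: ROC analysis is undefined"
        )
    return labels


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_ci(
    values: Sequence[float],
    labels: Sequence[bool],
    alpha: float = ALPHA,
) -> AucResult:
    """Mann–Whitney AUC with a DeLong 95% CI, truncated to [0, 1].

    Orientation is fixed: higher values predict the high class; AUC < 0.5
    is reported as-is.  Discriminative ⇔ lower CI bound > 0.5.  With
    perfectly separated classes the DeLong variance is 0 and the CI
    degenerates to a point.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise InputError("values and labels differ in length")
    pos = values[labels]
    neg = values[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise InputError("both classes must be present for ROC analysis")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    if m >= 2 and n >= 2:
        var = v01.var(ddof=1) / m + v10.var(ddof=1) / n
        se = float(np.sqrt(var))
        z = stats.norm.ppf(1 - alpha / 2)
        ci_low = max(0.0, auc - z * se)
        ci_high = min(1.0, auc + z * se)
    else:  # a CI needs at least two observations per class
        ci_low, ci_high = 0.0, 1.0
    return AucResult(
        auc=float(auc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        discriminative=bool(ci_low > 0.5),
    )


ASSOC_COLUMNS = [
    "level",
    "mean_rpm",
    "sd_rpm",
    "dynamic_range",
    "rho",
    "candidate",
    "p_perm",
    "p_adj",
    "significant",
    "auc",
    "auc_ci_low",
    "auc_ci_high",
    "discriminative",
    "note",
]


def screen(
    rpm_matrix: CountMatrix,
    scores: Mapping[str, float] | Sequence[float],
    summaries: pd.DataFrame | None = None,
    rho_threshold: float = RHO_THRESHOLD,
    alpha: float = ALPHA,
    roc_cutoff: float = ROC_CUTOFF,
    perm_config: PermutationConfig | None = None,
) -> pd.DataFrame:
    """Run the full per-feature association screen on an RPM matrix.

    ``rpm_matrix`` should already be restricted to abundance-filter passers;
    ``summaries`` (the abundance table) supplies mean/SD/dynamic range for
    the report.  Returns one row per feature (index = feature_id).  Features
    with undefined ρ (constant abundance) are retained with a ``note`` and
    excluded from candidacy.  ROC columns are NaN when the cohort is
    single-class at the cutoff.
    """
    perm_config = perm_config or PermutationConfig()
    if isinstance(scores, Mapping):
        try:
            score_vec = np.array([float(scores[s]) for s in rpm_matrix.sample_ids])
        except KeyError as e:
            raise InputError(f"sample {e.args[0]!r} missing from scores") from None
    else:
        score_vec = np.asarray(scores, dtype=float)
        if len(score_vec) != rpm_matrix.n_samples:
            raise InputError("scores length does not match matrix samples")

    values = rpm_matrix.data.to_numpy(dtype=float)
    feat_std, feat_const = _standardize_rows(_rank_rows(values))
    sc_std, sc_const = _standardize_rows(_rank_rows(score_vec))
    if sc_const:
        raise InputError("clinical score is constant across the cohort")
    rho = feat_std @ sc_std
    rho[feat_const] = np.nan

    df = pd.DataFrame(index=pd.Index(rpm_matrix.feature_ids, name="feature_id"))
    df["level"] = rpm_matrix.level
    if summaries is not None:
        df["mean_rpm"] = summaries["mean_rpm"].reindex(df.index)
        df["sd_rpm"] = summaries["sd_rpm"].reindex(df.index)
        df["dynamic_range"] = summaries["dynamic_range"].reindex(df.index)
    else:
        df["mean_rpm"] = values.mean(axis=1)
        df["sd_rpm"] = values.std(axis=1, ddof=1)
        vmin, vmax = values.min(axis=1), values.max(axis=1)
        df["dynamic_range"] = np.where(vmin > 0, vmax / np.where(vmin > 0, vmin, 1), np.nan)
    df["rho"] = rho
    df["candidate"] = ~np.isnan(rho) & (np.abs(rho) >= rho_threshold)
    df["note"] = np.where(feat_const, "constant abundance: rho undefined", "")

    # permutation test on candidates only, one shared shuffling stream
    df["p_perm"] = np.nan
    df["p_adj"] = np.nan
    cand_mask = df["candidate"].to_numpy()
    if cand_mask.any():
        p_perm, _ = permutation_pvalues(values[cand_mask], score_vec, perm_config)
        df.loc[cand_mask, "p_perm"] = p_perm
        # the BH family is every feature the screen tested, not only the
        # candidates that went on to permutation testing
        n_family = int((~np.isnan(rho)).sum())
        df.loc[cand_mask, "p_adj"] = bh_adjust(p_perm, family_size=n_family)
    df["significant"] = df["p_adj"] < alpha

    df["auc"] = np.nan
    df["auc_ci_low"] = np.nan
    df["auc_ci_high"] = np.nan
    df["discriminative"] = False
    try:
        labels = stratify_high_low(score_vec, roc_cutoff)
    except InputError:
        df.loc[df["note"] == "", "note"] = "single-class cohort: ROC skipped"
    else:
        for i, fid in enumerate(df.index):
            res = roc_auc_ci(values[i], labels, alpha)
            df.loc[fid, ["auc", "auc_ci_low", "auc_ci_high"]] = (
                res.auc,
                res.ci_low,
                res.ci_high,
            )
            df.loc[fid, "discriminative"] = res.discriminative
    return df[ASSOC_COLUMNS]


def _gt(a: float, b: float) -> bool:
    """Strict comparison in which an undefined side never wins."""
    return bool(np.isfinite(a) and np.isfinite(b) and a > b)


def compare_isomir_vs_parent(
    isomir_assoc: pd.DataFrame,
    mirna_assoc: pd.DataFrame,
    parent_of: Mapping[str, str],
    seed_changing: Iterable[str] = (),
    mirna_rpm: CountMatrix | None = None,
    scores: Sequence[float] | None = None,
    roc_cutoff: float = ROC_CUTOFF,
) -> pd.DataFrame:
    """Superiority comparison for every candidate isomiR against its parent.

    A parent that never entered permutation testing (not a candidate, or
    absent from the miRNA screen because it failed the abundance filter)
    contributes p_adj = 1; its ρ/AUC/dynamic range are taken from the screen
    table when available, else recomputed from ``mirna_rpm``.  Undefined
    dynamic ranges or AUCs never count as larger/higher.
    """
    seed_changing = set(seed_changing)
    rows = []
    for fid, iso in isomir_assoc[isomir_assoc["candidate"]].iterrows():
        parent = parent_of.get(fid)
        if parent is None:
            raise InputError(f"candidate isomiR {fid} has no parent assignment")
        if parent in mirna_assoc.index:
            par = mirna_assoc.loc[parent]
            par_rho = par["rho"]
            par_padj = par["p_adj"] if np.isfinite(par["p_adj"]) else 1.0
            par_dyn = par["dynamic_range"]
            par_auc = par["auc"]
            par_sig = bool(par["significant"])
        elif mirna_rpm is not None and scores is not None and parent in mirna_rpm.data.index:
            vals = mirna_rpm.data.loc[parent].to_numpy(dtype=float)
            par_rho = spearman_rho(vals, scores)
            par_padj = 1.0
            vmin, vmax = vals.min(), vals.max()
            par_dyn = vmax / vmin if vmin > 0 else np.nan
            try:
                par_auc = roc_auc_ci(vals, stratify_high_low(scores, roc_cutoff)).auc
            except InputError:
                par_auc = np.nan
            par_sig = False
        else:
            par_rho, par_padj, par_dyn, par_auc, par_sig = np.nan, 1.0, np.nan, np.nan, False

        iso_padj = iso["p_adj"] if np.isfinite(iso["p_adj"]) else 1.0
        stronger_rho = _gt(abs(iso["rho"]), abs(par_rho) if np.isfinite(par_rho) else 0.0)
        lower_padj = bool(iso_padj < par_padj)
        larger_dyn = _gt(iso["dynamic_range"], par_dyn)
        higher_auc = _gt(iso["auc"], par_auc)
        rows.append(
            {
                "isomir_id": fid,
                "parent_id": parent,
                "rho_isomir": iso["rho"],
                "rho_mirna": par_rho,
                "p_adj_isomir": iso_padj,
                "p_adj_mirna": par_padj,
                "stronger_rho": stronger_rho,
                "lower_padj": lower_padj,
                "larger_dynamic_range": larger_dyn,
                "higher_auc": higher_auc,
                "superior": stronger_rho and lower_padj and larger_dyn and higher_auc,
                "isomir_only": bool(iso["significant"]) and not par_sig,
                "seed_changing": fid in seed_changing,
            }
        )
    columns = [
        "isomir_id",
        "parent_id",
        "rho_isomir",
        "rho_mirna",
        "p_adj_isomir",
        "p_adj_mirna",
        "stronger_rho",
        "lower_padj",
        "larger_dynamic_range",
        "higher_auc",
        "superior",
        "isomir_only",
        "seed_changing",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("isomir_id")
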