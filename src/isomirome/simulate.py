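"""Synthetic cohort generator for every input the pipeline consumes.

The generator stands in for a small plasma small-RNA-seq study: 13 patient
libraries scored on a 0–99 cardiovascular-risk percentile, a catalog of
canonical miRNAs with precursor context, an isomiR repertoire per miRNA, a
count matrix with planted score–abundance associations, hemolysis qPCR
values, and a cholesterol-efflux plate.  Its statistical structure is
controlled so every downstream stage is testable without real data:

* **Null features** fluctuate around a feature-specific baseline with
  gamma-overdispersed (negative-binomial-like) count noise, independent of
  the score.
* **Planted features** have expected log-abundance linear in the normal
  scores of the clinical-score ranks, mixed through a Gaussian copula whose
  coefficient a = 2·sin(π·ρ/6) makes the population Spearman correlation
  equal the requested ``effect_rho``.
* **isomiR-only scenarios** plant a positive signal on a seed-changing
  variant and the mirrored negative signal on a sibling of the same parent,
  so the parent's aggregated counts are symmetric in the latent signal and
  rank-uncorrelated with the score — the headline case in which an isomiR
  is informative while its miRNA is not.
* One **outlier library** can be injected by zeroing ~70% of the features
  that every other library detects, for the QC stage to find.

Counts are drawn per library as a multinomial over the per-sample intensity
profile, with the total fixed inside ``depth_range``.  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .isomir import (
    CanonicalMiRNA,
    classify_isomir,
    feature_id_for,
)
from .matrix import CountMatrix

RNA_BASES = "ACGU"
FLANK_LEN = 10
LOG_SIGMA = 0.9  # log-scale spread of planted feature abundance

# A handful of dominant, across-patient-stable miRNAs carry most plasma
# small-RNA reads; they pin the RPM denominator so that planted signals
# (a few percent of the library) cannot leak into null features' RPM ranks
# through the library total.
N_CORE_PARENTS = 6
CORE_DISPERSION = 0.02


@dataclass
class SimulationConfig:
    """The stated world of the synthetic cohort.

    Defaults mirror the emulated study: 13 libraries, one degenerate
    library injected for QC to remove, two planted miRNA-level signals and
    one isomiR-only seed-changing scenario.  The planted population rank
    correlation is 0.9: at n = 12 analyzed libraries, only associations of
    this strength survive a multiplicity correction over the full screened
    family, which is the regime the reported strong hits occupy.
    """

    n_samples: int = 13
    n_mirnas: int = 60
    isomirs_per_mirna: tuple[int, int] = (2, 6)
    n_planted_mirna: int = 2
    n_planted_isomir_only: int = 1
    effect_rho: float = 0.9
    depth_range: tuple[int, int] = (500_000, 1_500_000)
    dispersion: float = 0.2
    outlier_library: bool = True
    n_hemolytic: int = 0
    n_aberrant_replicates: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.n_mirnas < 1:
            raise ConfigurationError("n_mirnas must be >= 1: empty catalog forbidden")
        lo, hi = self.isomirs_per_mirna
        if not (0 <= lo <= hi):
            raise ConfigurationError("isomirs_per_mirna must be a non-negative range")
        if not 0 < self.effect_rho <= 1:
            raise ConfigurationError("effect_rho must be in (0, 1]")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigurationError("depth_range must be positive and ordered")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if self.n_planted_mirna + self.n_planted_isomir_only > self.n_mirnas:
            raise ConfigurationError("more planted features than miRNAs")
        if self.n_hemolytic >= self.n_samples:
            raise ConfigurationError("cannot make every sample hemolytic")

    def rng(self, stream: int) -> np.random.Generator:
        """A named deterministic RNG stream derived from ``rng_seed``."""
        return np.random.default_rng([self.rng_seed, stream])


@dataclass
class IsomirTemplate:
    """A generated isomiR sequence before counts: identity plus true class."""

    isomir_id: str
    sequence: str
    parent: str
    variant_class: str
    seed_changing: bool
    operation: str  # the generating edit, e.g. "5p_trim_1"


@dataclass
class SyntheticTruth:
    """Ground truth of the generated dataset, for round-trip testing."""

    planted_feature_ids: list[tuple[str, int]] = field(default_factory=list)
    planted_mirna_ids: list[tuple[str, int]] = field(default_factory=list)
    isomir_only: list[tuple[str, str]] = field(default_factory=list)  # (isomir, parent)
    outlier_library_id: str | None = None
    seed_changing_ids: list[str] = field(default_factory=list)
    template_classes: dict[str, tuple[str, bool]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["template_classes"] = {k: list(v) for k, v in self.template_classes.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            planted_feature_ids=[tuple(x) for x in d["planted_feature_ids"]],
            planted_mirna_ids=[tuple(x) for x in d["planted_mirna_ids"]],
            isomir_only=[tuple(x) for x in d["isomir_only"]],
            outlier_library_id=d["outlier_library_id"],
            seed_changing_ids=list(d["seed_changing_ids"]),
            template_classes={k: (v[0], bool(v[1])) for k, v in d["template_classes"].items()},
        )


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


def generate_canonical_catalog(config: SimulationConfig) -> dict[str, CanonicalMiRNA]:
    """Random mature sequences (20–24 nt) with 10 nt precursor flanks."""
    config.validate()
    rng = config.rng(1)
    catalog: dict[str, CanonicalMiRNA] = {}
    for i in range(config.n_mirnas):
        mirna_id = f"syn-miR-{i + 1:04d}"
        length = int(rng.integers(20, 25))
        catalog[mirna_id] = CanonicalMiRNA(
            mirna_id=mirna_id,
            mature_seq=_random_rna(rng, length),
            precursor_5p_flank=_random_rna(rng, FLANK_LEN),
            precursor_3p_flank=_random_rna(rng, FLANK_LEN),
        )
    return catalog


def _make_variant(
    op: str, canonical: CanonicalMiRNA, rng: np.random.Generator
) -> tuple[str, str, bool] | None:
    """Apply one generating edit; returns (sequence, class, seed_changing)."""
    m = canonical.mature_seq
    f5, f3 = canonical.precursor_5p_flank, canonical.precursor_3p_flank
    if op.startswith("5p_trim"):
        k = int(op[-1])
        return m[k:], "iso_5p", True
    if op.startswith("5p_ext"):
        k = int(op[-1])
        return f5[-k:] + m, "iso_5p", True
    if op.startswith("3p_trim"):
        k = int(op[-1])
        return m[:-k], "iso_3p", False
    if op.startswith("3p_ext"):
        k = int(op[-1])
        return m + f3[:k], "iso_3p", False
    if op == "nta":
        # non-templated 3' addition: pick A or U, avoiding the templated base
        choices = [b for b in "AU" if b != f3[0]] or ["A"]
        base = choices[int(rng.integers(len(choices)))]
        if base == f3[0]:
            return None
        return m + base, "iso_3p", False
    if op == "sub":
        pos = int(rng.integers(len(m)))  # 0-based
        base = rng.choice([b for b in RNA_BASES if b != m[pos]])
        seq = m[:pos] + base + m[pos + 1 :]
        return seq, "polymorphic", 2 <= pos + 1 <= 7
    if op == "mixed":
        return f5[-1:] + m + f3[:1], "mixed", True  # 5' ext + 3' ext, templated
    raise ValueError(op)


_VARIANT_OPS = [
    "5p_trim_1",
    "5p_trim_2",
    "5p_ext_1",
    "5p_ext_2",
    "3p_trim_1",
    "3p_trim_2",
    "3p_ext_1",
    "3p_ext_2",
    "nta",
    "sub",
    "mixed",
]


def generate_isomir_repertoire(
    catalog: Mapping[str, CanonicalMiRNA], config: SimulationConfig
) -> list[IsomirTemplate]:
    """Canonical sequence plus sampled variants for every catalog entry.

    The first variant of every parent is the 1 nt 5'-trim (a seed-changing
    isomiR), guaranteeing each parent can host an isomiR-only scenario; the
    remaining variants are drawn uniformly from the edit vocabulary.
    Sequences are unique within a parent.
    """
    if not catalog:
        raise ConfigurationError("catalog is empty")
    config.validate()
    rng = config.rng(2)
    lo, hi = config.isomirs_per_mirna
    templates: list[IsomirTemplate] = []
    for mirna_id, canonical in catalog.items():
        seen = {canonical.mature_seq}
        templates.append(
            IsomirTemplate(
                isomir_id=feature_id_for(mirna_id, canonical.mature_seq),
                sequence=canonical.mature_seq,
                parent=mirna_id,
                variant_class="canonical",
                seed_changing=False,
                operation="canonical",
            )
        )
        n_var = int(rng.integers(lo, hi + 1))
        ops = ["5p_trim_1"] + list(rng.choice(_VARIANT_OPS, size=max(n_var * 3, 3)))
        made = 0
        for op in ops:
            if made >= max(n_var, 1):
                break
            out = _make_variant(op, canonical, rng)
            if out is None:
                continue
            seq, vclass, seedch = out
            if seq in seen:
                continue
            seen.add(seq)
            templates.append(
                IsomirTemplate(
                    isomir_id=feature_id_for(mirna_id, seq),
                    sequence=seq,
                    parent=mirna_id,
                    variant_class=vclass,
                    seed_changing=seedch,
                    operation=op,
                )
            )
            made += 1
    return templates


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata: IDs, clinical score, and hemolysis Ct values.

    Scores are integers on the 0–99 percentile scale, drawn to span both
    sides of the 75th-percentile cutoff with roughly the 6-high/7-low split
    of the emulated cohort.  All samples pass the ΔCt < 7 hemolysis rule
    unless ``n_hemolytic`` failures are requested.
    """
    config.validate()
    rng = config.rng(3)
    n = config.n_samples
    high = rng.random(n) < 6 / 13
    scores = np.where(
        high,
        rng.integers(75, 100, size=n),
        rng.integers(0, 67, size=n),
    ).astype(int)
    # guarantee both risk classes are represented
    if not (scores >= 75).any():
        scores[int(rng.integers(n))] = int(rng.integers(75, 100))
    if not (scores < 75).any():
        scores[int(rng.integers(n))] = int(rng.integers(0, 67))

    ct_451a = rng.uniform(18.0, 22.0, size=n)
    delta = rng.uniform(2.0, 6.0, size=n)
    if config.n_hemolytic:
        which = rng.choice(n, size=config.n_hemolytic, replace=False)
        delta[which] = rng.uniform(7.5, 10.0, size=config.n_hemolytic)
    ct_23a = ct_451a + delta
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n)],
            "score": scores,
            "ct_mir23a": np.round(ct_23a, 2),
            "ct_mir451a": np.round(ct_451a, 2),
        }
    )


def rank_normal_scores(scores: Sequence[float]) -> np.ndarray:
    """Unit-variance normal scores of the clinical-score ranks (Blom)."""
    r = stats.rankdata(scores)
    u = stats.norm.ppf((r - 0.375) / (len(r) + 0.25))
    sd = u.std()
    return u / sd if sd > 0 else u


def planted_multipliers(
    scores: Sequence[float],
    effect_rho: float,
    rng: np.random.Generator,
    sign: int = 1,
    sigma: float = LOG_SIGMA,
    latent: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample abundance multipliers with Spearman(abundance, score) ≈ ρ.

    The latent z mixes the score's normal ranks with independent noise at
    Gaussian-copula weight a = 2·sin(π·ρ/6); the multiplier exp(σz − σ²/2)
    is a strictly monotone transform of z, so the rank correlation carries
    over.  Returns ``(multipliers, z)``; pass ``latent`` to reuse a z (e.g.
    with ``sign=-1`` for the compensating sibling of an isomiR-only pair).
    """
    u = rank_normal_scores(scores)
    a = min(2.0 * np.sin(np.pi * effect_rho / 6.0), 1.0)
    if latent is None:
        noise = rng.standard_normal(len(u))
        latent = a * u + np.sqrt(max(0.0, 1.0 - a * a)) * noise
    z = sign * latent
    return np.exp(sigma * z - sigma**2 / 2.0), latent


def generate_count_matrix(
    repertoire: Sequence[IsomirTemplate],
    cohort: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[CountMatrix, SyntheticTruth]:
    """IsomiR-level raw counts with planted structure and ground truth.

    Planted miRNA-level signals ride on the canonical isomiR of their
    parent; the first planted parent's canonical carries only ~45% of the
    parent's reads (so its isomiR out-performs the diluted aggregate —
    the superiority scenario), the others ~85%.  IsomiR-only scenarios put
    a +ρ signal on the forced seed-changing 5'-trim variant and the
    mirrored −ρ signal on a sibling so the aggregate stays null.
    """
    if not len(repertoire) or not len(cohort):
        raise ConfigurationError("repertoire and cohort must be non-empty")
    config.validate()
    rng = config.rng(4)
    scores = cohort["score"].to_numpy(dtype=float)
    n = len(cohort)
    sample_ids = list(cohort["sample_id"])

    by_parent: dict[str, list[IsomirTemplate]] = {}
    for t in repertoire:
        by_parent.setdefault(t.parent, []).append(t)
    parents = list(by_parent)

    n_special = config.n_planted_mirna + config.n_planted_isomir_only
    eligible = [p for p in parents if len(by_parent[p]) >= 3]
    if len(eligible) < n_special:
        raise ConfigurationError(
            f"only {len(eligible)} parents have enough isomiRs for "
            f"{n_special} planted scenarios"
        )
    special = list(rng.choice(eligible, size=n_special, replace=False)) if n_special else []
    planted_parents = special[: config.n_planted_mirna]
    isomir_only_parents = special[config.n_planted_mirna :]
    null_parents = [p for p in parents if p not in special]
    n_core = min(N_CORE_PARENTS, len(null_parents))
    core_parents = set(rng.choice(null_parents, size=n_core, replace=False)) if n_core else set()

    truth = SyntheticTruth()
    truth.template_classes = {
        t.isomir_id: (t.variant_class, t.seed_changing) for t in repertoire
    }
    truth.seed_changing_ids = [t.isomir_id for t in repertoire if t.seed_changing]

    # --- per-feature baselines (arbitrary intensity units ~ RPM) ---
    feature_ids: list[str] = [t.isomir_id for t in repertoire]
    fidx = {f: i for i, f in enumerate(feature_ids)}
    baseline = np.empty(len(feature_ids))
    for parent in parents:
        members = by_parent[parent]
        if parent in planted_parents or parent in isomir_only_parents:
            pbase = float(rng.lognormal(np.log(1200.0), 0.3))
        elif parent in core_parents:
            pbase = float(rng.lognormal(np.log(25_000.0), 0.3))
        else:
            pbase = float(rng.lognormal(np.log(8.0), 2.2))
        canonical = members[0]
        variants = members[1:]
        if parent in planted_parents:
            w_can = 0.45 if parent == planted_parents[0] else 0.85
        elif parent in isomir_only_parents:
            w_can = 0.30
        else:
            w_can = float(rng.uniform(0.4, 0.7))
        weights = {canonical.isomir_id: w_can}
        if variants:
            if parent in isomir_only_parents:
                # seed-changer and compensator get matched large shares
                w = np.full(len(variants), 0.1 / max(len(variants) - 2, 1))
                w[0] = 0.30
                if len(variants) > 1:
                    w[1] = 0.30
                w = w / w.sum() * (1 - w_can)
            else:
                w = rng.dirichlet(np.ones(len(variants))) * (1 - w_can)
            for t, wi in zip(variants, w):
                weights[t.isomir_id] = float(wi)
        for t in members:
            baseline[fidx[t.isomir_id]] = pbase * weights[t.isomir_id]

    # --- per-sample multipliers: gamma noise, tight on the core parents ---
    mult = np.empty((len(feature_ids), n))
    disp = np.full(len(feature_ids), config.dispersion)
    for parent in core_parents:
        for t in by_parent[parent]:
            disp[fidx[t.isomir_id]] = min(CORE_DISPERSION, config.dispersion or CORE_DISPERSION)
    for i in range(len(feature_ids)):
        if disp[i] > 0:
            shape = 1.0 / disp[i]
            mult[i] = rng.gamma(shape, scale=1.0 / shape, size=n)
        else:
            mult[i] = 1.0

    signs = [1, 1] + [(-1) ** i for i in range(max(0, config.n_planted_mirna - 2))]
    for parent, sign in zip(planted_parents, signs):
        canonical = by_parent[parent][0]
        m, _ = planted_multipliers(scores, config.effect_rho, rng, sign=sign)
        mult[fidx[canonical.isomir_id]] = m
        truth.planted_feature_ids.append((canonical.isomir_id, sign))
        truth.planted_mirna_ids.append((parent, sign))

    for parent in isomir_only_parents:
        members = by_parent[parent]
        seed_changer, compensator = members[1], members[2]
        m_pos, latent = planted_multipliers(scores, config.effect_rho, rng, sign=1)
        m_neg, _ = planted_multipliers(
            scores, config.effect_rho, rng, sign=-1, latent=latent
        )
        mult[fidx[seed_changer.isomir_id]] = m_pos
        mult[fidx[compensator.isomir_id]] = m_neg
        truth.planted_feature_ids.append((seed_changer.isomir_id, 1))
        truth.planted_feature_ids.append((compensator.isomir_id, -1))
        truth.isomir_only.append((seed_changer.isomir_id, parent))

    intensity = baseline[:, None] * mult

    # --- multinomial counts at a library depth inside depth_range ---
    # Depths are evenly spaced over the range, in shuffled order: the smooth
    # depth-driven spread of detection counts then dominates per-feature
    # Bernoulli jitter, as it does at the real scale of hundreds of
    # thousands of features, keeping the QC Tukey fence well calibrated.
    # (geometric spacing: detection counts are near-linear in log depth)
    depths = rng.permutation(
        np.geomspace(config.depth_range[0], config.depth_range[1], n).astype(np.int64)
    )
    counts = np.empty_like(intensity, dtype=np.int64)
    for s in range(n):
        p = intensity[:, s] / intensity[:, s].sum()
        counts[:, s] = rng.multinomial(depths[s], p)

    # --- degrade one library into an outlier ---
    if config.outlier_library:
        out_idx = int(rng.integers(n))
        others = np.delete(np.arange(n), out_idx)
        common = np.flatnonzero((counts[:, others] >= 1).all(axis=1))
        kill = rng.choice(common, size=int(round(0.7 * len(common))), replace=False)
        counts[kill, out_idx] = 0
        truth.outlier_library_id = sample_ids[out_idx]

    data = pd.DataFrame(
        counts,
        index=pd.Index(feature_ids, name="feature_id"),
        columns=sample_ids,
    )
    return CountMatrix(data, level="isomir", normalized=False), truth


def generate_efflux_plate(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Triplicate efflux CPM readings per sample plus one blank well.

    Specific efflux is planted inversely proportional to the clinical score
    (plus noise), emulating the reported negative RCT–risk association.
    ``n_aberrant_replicates`` samples get one replicate displaced far enough
    to trip the 1.15-SD triplicate rule (the emulated assay dropped one
    replicate in 5 of 13 samples).
    """
    if not len(cohort):
        raise ConfigurationError("cohort is empty")
    config.validate()
    rng = config.rng(5)
    blank_total = float(rng.uniform(3.0, 5.0))
    rows = []
    n_aberrant = min(config.n_aberrant_replicates, len(cohort))
    aberrant = set(
        rng.choice(cohort["sample_id"], size=n_aberrant, replace=False)
    )
    for _, srow in cohort.iterrows():
        sid, score = srow["sample_id"], float(srow["score"])
        spec = 11.0 - 0.08 * score + rng.normal(0.0, 1.5)
        spec = float(np.clip(spec, 0.5, 25.0))
        totals = spec + blank_total + rng.normal(0.0, 0.15, size=3)
        if sid in aberrant:
            which = int(rng.integers(3))
            totals[which] += float(rng.choice([-1.0, 1.0]) * rng.uniform(8.0, 14.0))
            totals[which] = float(np.clip(totals[which], 0.5, 80.0))
        for rep, total in enumerate(totals, start=1):
            lysate = float(rng.uniform(6e4, 9e4))
            medium = total / (100.0 - total) * lysate
            rows.append(
                {
                    "sample_id": sid,
                    "replicate_index": rep,
                    "cpm_medium": round(medium, 1),
                    "cpm_lysate": round(lysate, 1),
                    "is_blank": 0,
                }
            )
    lysate = float(rng.uniform(6e4, 9e4))
    medium = blank_total / (100.0 - blank_total) * lysate
    rows.append(
        {
            "sample_id": "BLANK",
            "replicate_index": 1,
            "cpm_medium": round(medium, 1),
            "cpm_lysate": round(lysate, 1),
            "is_blank": 1,
        }
    )
    return pd.DataFrame(rows)
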