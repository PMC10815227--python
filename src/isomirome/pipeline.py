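"""End-to-end orchestration: QC → RPM → filter → screen → superiority → efflux.

Stages run in the study's order: hemolysis gate, library outlier removal,
RPM normalization, isomiR→miRNA aggregation, the dual abundance filter at
both levels, the Spearman screen with permutation p-values and BH
adjustment per level, ROC discrimination at the 75th-percentile cutoff, the
isomiR-vs-parent superiority comparison, and (when a plate table is given)
cholesterol-efflux associations.  Every sample removal is logged with its
reason, and a funnel report tracks feature counts through the stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import abundance, association, efflux as efflux_mod, io, qc
from .errors import ConfigurationError, InputError
from .isomir import parent_map, parse_isomir_table, seed_changing_ids
from .matrix import CountMatrix
from .simulate import (
    SimulationConfig,
    generate_canonical_catalog,
    generate_cohort,
    generate_count_matrix,
    generate_efflux_plate,
    generate_isomir_repertoire,
)

FIXTURE_NAMES = {
    "catalog": "catalog.fasta",
    "precursor": "precursors.fasta",
    "isomir": "isomir_counts.tsv",
    "samples": "samples.tsv",
    "efflux": "efflux_plate.tsv",
    "truth": "truth.json",
}


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run; defaults are the study's."""

    catalog_fasta: str | Path
    isomir_tsv: str | Path
    samples_tsv: str | Path
    precursor_fasta: str | Path | None = None
    efflux_tsv: str | Path | None = None
    out_dir: str | Path | None = None
    mean_rpm_min: float = 5.0
    max_rpm_min: float = 50.0
    rho_threshold: float = 0.55
    n_perm: int = 10_000
    alpha: float = 0.05
    roc_cutoff: float = 75.0
    rng_seed: int = 0
    strict_qc: bool = True

    def validate(self) -> None:
        if self.mean_rpm_min < 0 or self.max_rpm_min < 0 or self.rho_threshold < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class StageCounts:
    n_total_features: int = 0
    n_passed_abundance: int = 0
    n_candidates: int = 0
    n_significant: int = 0
    n_discriminative: int = 0


@dataclass
class FunnelReport:
    mirna: StageCounts = field(default_factory=StageCounts)
    isomir: StageCounts = field(default_factory=StageCounts)
    n_superior_isomirs: int = 0
    n_isomir_only: int = 0
    n_seed_changing_isomir_only: int = 0
    libraries_removed: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    funnel: FunnelReport
    qc_report: pd.DataFrame
    abundance_mirna: pd.DataFrame
    abundance_isomir: pd.DataFrame
    assoc_mirna: pd.DataFrame
    assoc_isomir: pd.DataFrame
    superiority: pd.DataFrame
    efflux: pd.DataFrame | None
    efflux_associations: pd.DataFrame | None
    rejects: pd.DataFrame
    log: list[str]


def _stage_counts(assoc: pd.DataFrame, n_total: int, n_passed: int) -> StageCounts:
    sig = assoc["significant"]
    return StageCounts(
        n_total_features=n_total,
        n_passed_abundance=n_passed,
        n_candidates=int(assoc["candidate"].sum()),
        n_significant=int(sig.sum()),
        n_discriminative=int((sig & assoc["discriminative"]).sum()),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    log: list[str] = []
    log.append(f"thresholds: mean_rpm>{config.mean_rpm_min} max_rpm>{config.max_rpm_min} "
               f"|rho|>={config.rho_threshold} n_perm={config.n_perm} alpha={config.alpha} "
               f"roc_cutoff={config.roc_cutoff} seed={config.rng_seed}")

    catalog = io.load_catalog(config.catalog_fasta, config.precursor_fasta)
    records, raw_isomir, rejects = parse_isomir_table(config.isomir_tsv, catalog)
    if len(rejects):
        log.append(f"rejected {len(rejects)} rows with unknown parent miRNA")
    samples = io.load_samples(config.samples_tsv)
    samples = samples.set_index("sample_id", drop=False)

    # --- QC: hemolysis gate ---
    removed: list[str] = []
    for sid, row in samples.iterrows():
        res = qc.hemolysis_check(row["ct_mir23a"], row["ct_mir451a"], sample_id=sid)
        if not res.passed:
            msg = f"sample {sid}: hemolytic (delta Ct = {res.delta_ct:.2f} >= 7)"
            if config.strict_qc:
                log.append(f"removed {msg}")
                removed.append(sid)
            else:
                log.append(f"warning (kept): {msg}")
    analysis = raw_isomir.drop_samples(removed)

    # --- QC: library outlier scan ---
    reports = qc.library_outlier_scan(analysis)
    qc_frame = qc.qc_report_frame(reports)
    for r in reports:
        if r.outlier:
            msg = (
                f"library {r.sample_id}: outlier "
                f"(detects {r.n_in_common5} of the >=5-library common features, "
                f"median inter-library rho = {r.median_intercorrelation:.3f})"
            )
            if config.strict_qc:
                log.append(f"removed {msg}")
                removed.append(r.sample_id)
            else:
                log.append(f"warning (kept): {msg}")
    analysis = raw_isomir.drop_samples(removed)
    if analysis.n_samples < 4:
        raise InputError(
            f"only {analysis.n_samples} libraries survive QC; need at least 4"
        )
    scores = {
        sid: float(samples.loc[sid, "score"])
        for sid in analysis.sample_ids
    }
    score_vec = np.array([scores[s] for s in analysis.sample_ids])

    # --- abundance: RPM at both levels ---
    parents = parent_map(records)
    raw_mirna = abundance.aggregate_mirna(analysis, parents)
    rpm_isomir = abundance.rpm_normalize(analysis)
    rpm_mirna = abundance.rpm_normalize(raw_mirna)
    ab_isomir = abundance.abundance_filter(rpm_isomir, config.mean_rpm_min, config.max_rpm_min)
    ab_mirna = abundance.abundance_filter(rpm_mirna, config.mean_rpm_min, config.max_rpm_min)

    perm_cfg = association.PermutationConfig(n_perm=config.n_perm, rng_seed=config.rng_seed)
    kept_isomir = list(ab_isomir.index[ab_isomir["passed_filter"]])
    kept_mirna = list(ab_mirna.index[ab_mirna["passed_filter"]])
    assoc_isomir = association.screen(
        rpm_isomir.select_features(kept_isomir),
        score_vec,
        summaries=ab_isomir,
        rho_threshold=config.rho_threshold,
        alpha=config.alpha,
        roc_cutoff=config.roc_cutoff,
        perm_config=perm_cfg,
    )
    assoc_mirna = association.screen(
        rpm_mirna.select_features(kept_mirna),
        score_vec,
        summaries=ab_mirna,
        rho_threshold=config.rho_threshold,
        alpha=config.alpha,
        roc_cutoff=config.roc_cutoff,
        perm_config=perm_cfg,
    )

    superiority = association.compare_isomir_vs_parent(
        assoc_isomir,
        assoc_mirna,
        parents,
        seed_changing=seed_changing_ids(records),
        mirna_rpm=rpm_mirna,
        scores=score_vec,
        roc_cutoff=config.roc_cutoff,
    )

    funnel = FunnelReport(
        mirna=_stage_counts(assoc_mirna, rpm_mirna.n_features, len(kept_mirna)),
        isomir=_stage_counts(assoc_isomir, rpm_isomir.n_features, len(kept_isomir)),
        n_superior_isomirs=int(superiority["superior"].sum()),
        n_isomir_only=int(superiority["isomir_only"].sum()),
        n_seed_changing_isomir_only=int(
            (superiority["isomir_only"] & superiority["seed_changing"]).sum()
        ),
        libraries_removed=list(removed),
    )

    # --- efflux stage (optional; never alters the association outputs) ---
    efflux_table = None
    efflux_assoc = None
    if config.efflux_tsv is not None:
        plate = io.load_efflux(config.efflux_tsv)
        plate = plate[
            plate["is_blank"].astype(bool)
            | plate["sample_id"].isin(analysis.sample_ids)
        ]
        efflux_table = efflux_mod.process_plate(plate)
        sig_seed = [
            fid
            for fid in assoc_isomir.index[assoc_isomir["significant"]]
            if fid in seed_changing_ids(records)
        ]
        feature_rpms = rpm_isomir.data.loc[sig_seed] if sig_seed else None
        try:
            efflux_assoc = efflux_mod.efflux_associations(
                efflux_table, scores, feature_rpms
            )
        except InputError as e:
            log.append(f"efflux associations skipped: {e}")
    else:
        log.append("no efflux table provided; efflux stage skipped")

    result = PipelineResult(
        funnel=funnel,
        qc_report=qc_frame,
        abundance_mirna=ab_mirna,
        abundance_isomir=ab_isomir,
        assoc_mirna=assoc_mirna,
        assoc_isomir=assoc_isomir,
        superiority=superiority,
        efflux=efflux_table,
        efflux_associations=efflux_assoc,
        rejects=rejects,
        log=log,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _fmt_assoc(assoc: pd.DataFrame) -> pd.DataFrame:
    """Report view of a screen table: ND in the discriminative column."""
    out = assoc.copy()
    out["discriminative"] = np.where(
        out["discriminative"], out["auc"].round(3).astype(str), "ND"
    )
    return out


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_csv(out_dir / "qc_report.tsv", sep="\t")
    result.abundance_mirna.to_csv(out_dir / "abundance_mirna.tsv", sep="\t")
    result.abundance_isomir.to_csv(out_dir / "abundance_isomir.tsv", sep="\t")
    _fmt_assoc(result.assoc_mirna).to_csv(out_dir / "assoc_mirna.tsv", sep="\t")
    _fmt_assoc(result.assoc_isomir).to_csv(out_dir / "assoc_isomir.tsv", sep="\t")
    result.superiority.to_csv(out_dir / "superiority.tsv", sep="\t")
    if result.efflux is not None:
        result.efflux.to_csv(out_dir / "efflux.tsv", sep="\t")
    if result.efflux_associations is not None:
        result.efflux_associations.to_csv(
            out_dir / "efflux_associations.tsv", sep="\t", index=False
        )
    (out_dir / "funnel.json").write_text(json.dumps(result.funnel.to_dict(), indent=2))
    (out_dir / "run.log").write_text("\n".join(result.log) + "\n")


def make_fixtures(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic dataset; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = generate_canonical_catalog(config)
    repertoire = generate_isomir_repertoire(catalog, config)
    cohort = generate_cohort(config)
    matrix, truth = generate_count_matrix(repertoire, cohort, config)
    plate = generate_efflux_plate(cohort, config)

    paths = {k: out / v for k, v in FIXTURE_NAMES.items()}
    io.write_catalog(catalog, paths["catalog"], paths["precursor"])
    io.write_isomir_table(repertoire, matrix, paths["isomir"])
    io.write_samples(cohort, paths["samples"])
    io.write_efflux(plate, paths["efflux"])
    io.write_truth(truth, paths["truth"])
    return paths


def run_on_fixtures(
    fixture_paths: dict[str, Path],
    out_dir: str | Path | None = None,
    **overrides,
) -> PipelineResult:
    """Convenience: a RunConfig wired to :func:`make_fixtures` output."""
    config = RunConfig(
        catalog_fasta=fixture_paths["catalog"],
        precursor_fasta=fixture_paths["precursor"],
        isomir_tsv=fixture_paths["isomir"],
        samples_tsv=fixture_paths["samples"],
        efflux_tsv=fixture_paths.get("efflux"),
        out_dir=out_dir,
        **overrides,
    )
    return run_pipeline(config)
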