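"""The synthetic cohort generator: determinism, structure, calibration."""

import numpy as np
import pytest
from scipy import stats

from isomirome import (
    ConfigurationError,
    SimulationConfig,
    classify_isomir,
    generate_canonical_catalog,
    generate_cohort,
    generate_count_matrix,
    generate_efflux_plate,
    generate_isomir_repertoire,
)
from isomirome.abundance import aggregate_mirna, rpm_normalize


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_mirnas": 0},
            {"n_samples": 3},
            {"effect_rho": 0.0},
            {"effect_rho": 1.2},
            {"depth_range": (0, 100)},
            {"depth_range": (100, 50)},
            {"n_planted_mirna": 50, "n_planted_isomir_only": 50, "n_mirnas": 60},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs).validate()


class TestCatalog:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_mirnas=5, rng_seed=1)
        a = generate_canonical_catalog(cfg)
        b = generate_canonical_catalog(cfg)
        assert a == b

    def test_lengths_and_flanks(self):
        catalog = generate_canonical_catalog(SimulationConfig(n_mirnas=100, rng_seed=7))
        assert len(catalog) == 100
        for ref in catalog.values():
            assert 20 <= len(ref.mature_seq) <= 24
            assert len(ref.precursor_5p_flank) >= 5
            assert len(ref.precursor_3p_flank) >= 5
            assert set(ref.mature_seq) <= set("ACGU")

    def test_unique_ids(self, catalog):
        assert len(set(catalog)) == len(catalog)


class TestRepertoire:
    def test_roundtrip_classification_matches_generating_spec(self, catalog, repertoire):
        """Every generated variant reclassifies to its generating class."""
        for t in repertoire:
            ann = classify_isomir(t.sequence, catalog[t.parent])
            assert ann.variant_class == t.variant_class, t.operation
            assert ann.seed_changing == t.seed_changing, t.operation

    def test_sequences_unique_per_parent(self, repertoire):
        seen = set()
        for t in repertoire:
            key = (t.parent, t.sequence)
            assert key not in seen
            seen.add(key)

    def test_every_parent_has_canonical_and_seed_changer(self, catalog, repertoire):
        by_parent = {}
        for t in repertoire:
            by_parent.setdefault(t.parent, []).append(t)
        assert set(by_parent) == set(catalog)
        for members in by_parent.values():
            assert members[0].variant_class == "canonical"
            assert any(t.seed_changing for t in members)


class TestCohort:
    def test_default_no_hemolysis(self):
        cohort = generate_cohort(SimulationConfig(rng_seed=2))
        assert len(cohort) == 13
        assert ((cohort["ct_mir23a"] - cohort["ct_mir451a"]) < 7).all()

    def test_requested_hemolytic_sample(self):
        cohort = generate_cohort(SimulationConfig(n_hemolytic=1, rng_seed=2))
        delta = cohort["ct_mir23a"] - cohort["ct_mir451a"]
        assert (delta >= 7).sum() == 1

    def test_scores_span_risk_cutoff(self):
        cohort = generate_cohort(SimulationConfig(n_samples=12, rng_seed=5))
        assert (cohort["score"] >= 75).any()
        assert (cohort["score"] < 75).any()
        assert cohort["score"].between(0, 99).all()
        assert cohort["sample_id"].is_unique


class TestCountMatrix:
    def test_seeded_determinism(self, sim_config, repertoire, cohort):
        a, _ = generate_count_matrix(repertoire, cohort, sim_config)
        b, _ = generate_count_matrix(repertoire, cohort, sim_config)
        assert a.data.equals(b.data)

    def test_no_planting_requested(self, catalog, cohort):
        cfg = SimulationConfig(n_planted_mirna=0, n_planted_isomir_only=0, rng_seed=0)
        rep = generate_isomir_repertoire(catalog, cfg)
        _, truth = generate_count_matrix(rep, generate_cohort(cfg), cfg)
        assert truth.planted_feature_ids == []
        assert truth.isomir_only == []

    def test_counts_are_nonnegative_integers_within_depth(self, catalog):
        cfg = SimulationConfig(outlier_library=False, rng_seed=3)
        rep = generate_isomir_repertoire(catalog, cfg)
        matrix, _ = generate_count_matrix(rep, generate_cohort(cfg), cfg)
        assert (matrix.data.to_numpy() >= 0).all()
        totals = matrix.library_totals()
        assert (totals >= cfg.depth_range[0]).all()
        assert (totals <= cfg.depth_range[1]).all()

    def test_truth_ids_exist(self, counts_and_truth):
        matrix, truth = counts_and_truth
        ids = set(matrix.feature_ids)
        for fid, _ in truth.planted_feature_ids:
            assert fid in ids
        for fid, parent in truth.isomir_only:
            assert fid in ids
        assert truth.outlier_library_id in matrix.sample_ids
        assert set(truth.seed_changing_ids) <= ids

    def test_outlier_library_zeroes_common_features(self, counts_and_truth):
        matrix, truth = counts_and_truth
        out = truth.outlier_library_id
        others = [s for s in matrix.sample_ids if s != out]
        common = (matrix.data[others] >= 1).all(axis=1)
        frac_zero = (matrix.data.loc[common, out] == 0).mean()
        assert frac_zero > 0.5

    def test_large_n_calibration(self):
        """Planted ρ hits its target; nulls and parent aggregates stay null."""
        cfg = SimulationConfig(
            n_samples=200, effect_rho=0.95, outlier_library=False, rng_seed=7
        )
        catalog = generate_canonical_catalog(cfg)
        rep = generate_isomir_repertoire(catalog, cfg)
        cohort = generate_cohort(cfg)
        matrix, truth = generate_count_matrix(rep, cohort, cfg)
        rpm = rpm_normalize(matrix).data
        scores = cohort["score"].to_numpy(dtype=float)

        for fid, sign in truth.planted_feature_ids:
            rho = stats.spearmanr(rpm.loc[fid], scores).statistic
            assert rho * sign == pytest.approx(0.95, abs=0.05)

        parents = {t.isomir_id: t.parent for t in rep}
        agg = rpm_normalize(aggregate_mirna(matrix, parents)).data
        for _, parent in truth.isomir_only:
            assert abs(stats.spearmanr(agg.loc[parent], scores).statistic) < 0.3

        planted = {f for f, _ in truth.planted_feature_ids}
        null_rhos = []
        for fid in rpm.index:
            if fid in planted or rpm.loc[fid].std() == 0:
                continue
            null_rhos.append(stats.spearmanr(rpm.loc[fid], scores).statistic)
        null_rhos = np.array(null_rhos)
        assert abs(null_rhos.mean()) < 0.05
        assert np.quantile(np.abs(null_rhos), 0.95) < 0.15


class TestEffluxPlate:
    def test_structure_and_determinism(self, sim_config, cohort):
        a = generate_efflux_plate(cohort, sim_config)
        b = generate_efflux_plate(cohort, sim_config)
        assert a.equals(b)
        assert (a["is_blank"] == 1).sum() == 1
        per_sample = a[a["is_blank"] == 0].groupby("sample_id").size()
        assert (per_sample == 3).all()
        assert (a[["cpm_medium", "cpm_lysate"]] > 0).all().all()

    def test_aberrant_replicate_count(self, cohort):
        cfg = SimulationConfig(n_aberrant_replicates=2, rng_seed=4)
        plate = generate_efflux_plate(cohort, cfg)
        from isomirome import process_plate

        table = process_plate(plate)
        assert (table["n_retained"] == 2).sum() >= 2
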