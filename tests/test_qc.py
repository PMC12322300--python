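import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnfprot import (
    SimulationConfig,
    classify_missingness,
    filter_low_confidence,
    impute_below_lod,
    missingness_summary,
    simulate_study,
    ConfidenceFilter,
    LodMinimumImputer,
)
from cnfprot.qc import IMPUTE_LOD, LEAVE_MAR
from cnfprot.simulate import CENSORED_LOD

from conftest import make_design, make_matrix
from oracles import brute_force_missingness_labels


class TestConfidenceFilter:
    def test_joint_rule_on_five_protein_fixture(self):
        pvals = [0.01, 0.04, 0.06, 0.001, 0.049]
        max_pep = [3, 1, 5, 2, 2]
        pep = np.zeros((5, 4), dtype=int)
        pep[:, 0] = max_pep
        pep[:, 1:] = 1
        m = make_matrix(np.ones((5, 4)), id_pvalue=pvals, peptide_counts=pep)
        kept = filter_low_confidence(m)
        assert kept.protein_ids == ["P1", "P4", "P5"]

    def test_pvalue_boundary_is_strict(self):
        m = make_matrix(np.ones((2, 2)), id_pvalue=[0.05, 0.01])
        kept = filter_low_confidence(m)
        assert kept.protein_ids == ["P2"]

    def test_peptide_boundary_needs_two_somewhere(self):
        pep = np.array([[1, 1, 1], [2, 0, 0], [0, 1, 2]])
        m = make_matrix(np.ones((3, 3)), peptide_counts=pep)
        kept = filter_low_confidence(m)
        assert kept.protein_ids == ["P2", "P3"]

    def test_idempotent(self):
        m = make_matrix(np.ones((4, 3)), id_pvalue=[0.01, 0.06, 0.02, 0.03])
        once = filter_low_confidence(m)
        twice = filter_low_confidence(once)
        assert once.equals(twice)

    def test_empty_result_is_error(self):
        m = make_matrix(np.ones((2, 2)), id_pvalue=[0.9, 0.9])
        with pytest.raises(ValueError, match="every protein"):
            filter_low_confidence(m)

    def test_estimator_interface(self):
        m = make_matrix(np.ones((3, 2)), id_pvalue=[0.01, 0.2, 0.03])
        est = ConfidenceFilter().fit(m)
        assert est.kept_proteins_ == ["P1", "P3"]
        assert est.n_dropped_ == 1
        assert est.get_params() == {"p_max": 0.05, "min_peptides": 2}


def design_matrix_15(missing_cnf=0, missing_skin=0):
    """One protein over the 15+15 design with the given missing cell counts."""
    design = make_design(4, [3, 4, 4, 4])
    cnf = design.tissue_samples("cNF")
    skin = design.tissue_samples("skin")
    cols = cnf + skin
    q = np.full((1, 30), 5.0)
    data = pd.DataFrame(q, index=["P1"], columns=cols)
    data.loc["P1", cnf[:missing_cnf]] = np.nan
    data.loc["P1", skin[:missing_skin]] = np.nan
    m = make_matrix(data.to_numpy(), protein_ids=["P1"], sample_ids=cols)
    return m, design


class TestClassifyMissingness:
    def test_reliable_skin_excess_cnf_all_imputed(self):
        m, design = design_matrix_15(missing_cnf=5)  # 10/15 detected, 33% missing
        cls = classify_missingness(m, design)
        assert cls.n_labeled(IMPUTE_LOD) == 5
        assert cls.n_labeled(LEAVE_MAR) == 0

    def test_exactly_20_percent_missing_is_not_in_excess(self):
        m, design = design_matrix_15(missing_cnf=3, missing_skin=2)
        # skin 13/15 = 86.7% >= 80%; cNF missing exactly 3/15 = 20%
        cls = classify_missingness(m, design)
        assert cls.n_labeled(IMPUTE_LOD) == 0
        assert cls.n_labeled(LEAVE_MAR) == 5

    def test_both_tissues_unreliable_never_imputed(self):
        m, design = design_matrix_15(missing_cnf=4, missing_skin=4)  # 11/15 both
        cls = classify_missingness(m, design)
        assert cls.n_labeled(IMPUTE_LOD) == 0
        assert cls.n_labeled(LEAVE_MAR) == 8

    def test_excess_mode_labels_only_cells_beyond_allowance(self):
        m, design = design_matrix_15(missing_cnf=5)
        cls = classify_missingness(m, design, mode="excess")
        assert cls.n_labeled(IMPUTE_LOD) == 2  # 5 missing - 3 allowed
        assert cls.n_labeled(LEAVE_MAR) == 3

    def test_matches_brute_force_on_random_small_matrices(self):
        rng = np.random.default_rng(42)
        design = make_design(2, [2, 2])  # 4 lesions -> 8 samples
        cols = design.sample_ids
        tissue_of = list(design.data.set_index("sample_id").loc[cols, "tissue"])
        for trial in range(60):
            n_prot = rng.integers(1, 10)
            q = rng.uniform(1, 10, (n_prot, 8))
            mask = rng.random((n_prot, 8)) < rng.uniform(0, 0.6)
            q[mask] = np.nan
            m = make_matrix(q, sample_ids=cols)
            for mode in ("all", "excess"):
                cls = classify_missingness(m, design, mode=mode)
                expected = brute_force_missingness_labels(
                    ~np.isnan(q), tissue_of, mode=mode
                )
                np.testing.assert_array_equal(cls.labels.to_numpy(), expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        mask_bits=st.lists(st.booleans(), min_size=24, max_size=24),
        mode=st.sampled_from(["all", "excess"]),
    )
    def test_property_labels_match_oracle(self, mask_bits, mode):
        design = make_design(2, [2, 1])  # 3 lesions -> 6 samples
        cols = design.sample_ids
        tissue_of = list(design.data.set_index("sample_id").loc[cols, "tissue"])
        mask = np.array(mask_bits, dtype=bool).reshape(4, 6)
        q = np.full((4, 6), 3.0)
        q[mask] = np.nan
        m = make_matrix(q, sample_ids=cols)
        cls = classify_missingness(m, design, mode=mode)
        expected = brute_force_missingness_labels(~np.isnan(q), tissue_of, mode=mode)
        np.testing.assert_array_equal(cls.labels.to_numpy(), expected)

    def test_zero_tissue_samples_is_error(self):
        design = make_design(1, [2])
        skin_only = design.data[design.data["tissue"] == "skin"]
        m = make_matrix(np.ones((2, 2)), sample_ids=list(skin_only["sample_id"]))
        from cnfprot import SampleTable

        with pytest.raises(ValueError, match="no cNF samples"):
            classify_missingness(m, SampleTable(skin_only.copy()))


class TestImputation:
    def test_fully_observed_matrix_untouched(self, paired_design_15):
        cols = paired_design_15.sample_ids
        m = make_matrix(np.full((3, 30), 2.0), sample_ids=cols)
        cls = classify_missingness(m, paired_design_15)
        imputed, report = impute_below_lod(m, cls)
        assert report.n_imputed_total == 0
        assert imputed.equals(m)

    def test_imputed_cells_get_global_minimum(self):
        m, design = design_matrix_15(missing_cnf=5)
        # add a second, complete protein carrying the dataset minimum
        q = np.vstack([m.quantities.to_numpy(), np.full((1, 30), 0.25)])
        m2 = make_matrix(q, protein_ids=["P1", "P2"], sample_ids=m.sample_ids)
        imputer = LodMinimumImputer().fit(m2, design)
        imputed = imputer.transform(m2)
        assert imputer.global_minimum_ == 0.25
        filled = imputed.quantities.loc["P1"].iloc[:5]
        np.testing.assert_allclose(filled, 0.25)
        assert imputer.report_.n_imputed_total == 5
        assert imputer.report_.n_imputed_by_tissue == {"cNF": 5, "skin": 0}

    def test_observed_cells_never_modified(self, study):
        matrix, samples, _, _ = study
        filtered = filter_low_confidence(matrix)
        cls = classify_missingness(filtered, samples)
        imputed, _ = impute_below_lod(filtered, cls)
        obs = filtered.quantities.notna()
        before = filtered.quantities.where(obs)
        after = imputed.quantities.where(obs)
        pd.testing.assert_frame_equal(before, after)

    def test_imputation_idempotent(self, study):
        matrix, samples, _, _ = study
        filtered = filter_low_confidence(matrix)
        first = LodMinimumImputer().fit_transform(filtered, samples)
        imputer2 = LodMinimumImputer().fit(first, samples)
        second = imputer2.transform(first)
        assert imputer2.report_.n_imputed_total == 0
        assert second.equals(first)

    def test_report_counts_consistent(self, study):
        matrix, samples, _, _ = study
        filtered = filter_low_confidence(matrix)
        n_missing_before = filtered.n_missing()
        imputer = LodMinimumImputer().fit(filtered, samples)
        imputer.transform(filtered)
        rep = imputer.report_
        assert rep.n_imputed_total == sum(rep.n_imputed_by_tissue.values())
        assert rep.n_remaining_missing == n_missing_before - rep.n_imputed_total

    def test_strong_one_tissue_censoring_is_recovered(self):
        # cNF pushed far below the detection limit, skin far above: nearly
        # every truth-censored cell must be labeled for imputation
        cfg = SimulationConfig(
            n_terms=10, proteins_per_term=10, n_background_proteins=0,
            term_log_ratio=[-4.0] * 10, protein_baseline_sd=0.3,
            sd_protein=0.2, lod=16.0, mar_rate=0.0, seed=17,
        )
        matrix, samples, _, truth = simulate_study(cfg)
        cls = classify_missingness(matrix, samples)
        censored = truth.missingness_cause.to_numpy() == CENSORED_LOD
        labeled = cls.labels.to_numpy() == IMPUTE_LOD
        recall = labeled[censored].mean()
        assert recall >= 0.95


class TestMissingnessSummary:
    def test_complete_matrix_all_zero(self, paired_design_15):
        m = make_matrix(np.ones((4, 30)), sample_ids=paired_design_15.sample_ids)
        summary = missingness_summary(m, paired_design_15)
        assert all(v == 0 for v in summary["per_sample_missing_fraction"].values())
        assert all(
            d["frac_in_any_sample"] == 1.0 and d["frac_in_all_samples"] == 1.0
            for d in summary["per_donor_detection"].values()
        )

    def test_two_of_twenty_missing_is_ten_percent(self):
        q = np.ones((20, 3))
        q[0, 0] = np.nan
        q[1, 0] = np.nan
        m = make_matrix(q)
        summary = missingness_summary(m)
        assert summary["per_sample_missing_fraction"]["S1"] == pytest.approx(0.10)
        assert summary["per_sample_missing_fraction"]["S2"] == 0.0
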