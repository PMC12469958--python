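"""Synthetic cohort generator: determinism, planted-effect calibration,
spatial structure and the peptide-library companion."""

import numpy as np
import pandas as pd
import pytest

from msipredict.core import NED, RECPRO, ParameterError
from msipredict.simulate import (
    PROTON_MASS,
    CohortSpec,
    generate_cohort,
    generate_peptide_library,
    generate_transfer_cohort,
)


def _clean_spec(**overrides):
    """Spec without axis/baseline/batch complications for moment checks."""
    defaults = dict(
        n_patients_per_class=(10, 10),
        spectra_per_patient=(200, 200),
        n_features=40,
        n_signal_features=6,
        effect_size=1.0,
        subclone_fraction=0.0,
        margin_fraction=0.0,
        batch_sd=0.0,
        background_channels_per_gap=0,
        baseline_amplitude=0.0,
        slide_count=2,
        seed=11,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def _standardized_diff(data, truth, j):
    """Oracle: direct group-mean / pooled-SD computation on the log table."""
    y = data.outcome_per_spectrum().to_numpy()
    logs = np.log(data.intensities[:, j])
    a, b = logs[y == NED], logs[y == RECPRO]
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    return (a.mean() - b.mean()) / pooled


class TestGenerateCohort:
    def test_seed_determinism(self):
        spec = _clean_spec(spectra_per_patient=(20, 30))
        d1, t1 = generate_cohort(spec)
        d2, t2 = generate_cohort(spec)
        assert np.array_equal(d1.intensities, d2.intensities)
        assert d1.obs.equals(d2.obs)
        assert np.array_equal(t1.signal_feature_indices, t2.signal_feature_indices)
        assert np.array_equal(t1.subclone_mask, t2.subclone_mask)

    def test_default_cohort_shape(self):
        spec = CohortSpec(
            spectra_per_patient=(5, 8), n_features=30, n_signal_features=5, seed=3
        )
        data, truth = generate_cohort(spec)
        assert data.patients["patient_id"].nunique() == 31
        counts = data.patients["outcome"].value_counts()
        assert counts[RECPRO] == 20 and counts[NED] == 11

    def test_null_effect_gives_no_group_difference(self):
        data, truth = generate_cohort(_clean_spec(effect_size=0.0))
        diffs = [_standardized_diff(data, truth, j) for j in truth.signal_feature_indices]
        assert abs(np.mean(diffs)) < 0.05

    def test_planted_effect_matches_moment_oracle(self):
        # 20 patients x 500 px per class = 10,000 pixels per group; a small
        # patient random effect keeps the per-feature estimate within the
        # Monte-Carlo band (between-patient variation dominates it otherwise)
        data, truth = generate_cohort(
            _clean_spec(
                n_patients_per_class=(20, 20),
                spectra_per_patient=(500, 500),
                patient_sd=0.02,
            )
        )
        diffs = [_standardized_diff(data, truth, j) for j in truth.signal_feature_indices]
        for d in diffs:
            assert abs(d - 1.0) < 0.1
        assert abs(np.mean(diffs) - 1.0) < 0.05

    def test_direction_negative_means_lower_in_recpro(self):
        data, truth = generate_cohort(_clean_spec())
        assert np.all(truth.directions == -1)
        y = data.outcome_per_spectrum().to_numpy()
        j = truth.signal_feature_indices[0]
        logs = np.log(data.intensities[:, j])
        assert logs[y == RECPRO].mean() < logs[y == NED].mean()

    def test_label_permutation_destroys_signal(self):
        # per-feature AUC over >= 500 features concentrates at 0.5 when the
        # outcome labels carry no information
        from scipy.stats import rankdata

        spec = _clean_spec(
            n_features=600, n_signal_features=30, spectra_per_patient=(20, 20),
            n_patients_per_class=(10, 10),
        )
        data, truth = generate_cohort(spec)
        rng = np.random.default_rng(5)
        outcomes = data.patients.set_index("patient_id")["outcome"]
        permuted = pd.Series(
            rng.permutation(outcomes.to_numpy()), index=outcomes.index
        )
        y = data.obs["patient_id"].map(permuted).to_numpy()
        rec, ned = data.intensities[y == RECPRO], data.intensities[y == NED]
        n1 = rec.shape[0]
        ranks = rankdata(np.vstack([rec, ned]), axis=0)
        auc = (ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * ned.shape[0])
        assert abs(auc.mean() - 0.5) < 0.05

    def test_spatial_autocorrelation_decays(self):
        spec = _clean_spec(
            spectra_per_patient=(400, 400), spatial_correlation_length=2.0,
            n_patients_per_class=(2, 2),
        )
        data, truth = generate_cohort(spec)
        j = truth.signal_feature_indices[0]
        pid = data.patients["patient_id"].iloc[0]
        rows = data.obs["patient_id"] == pid
        grp = data.obs.loc[rows]
        img = np.full((grp["y"].max() + 1, grp["x"].max() + 1), np.nan)
        img[grp["y"], grp["x"]] = np.log(data.intensities[rows.to_numpy(), j])

        def lag_corr(lag):
            a, b = img[:, :-lag].ravel(), img[:, lag:].ravel()
            ok = np.isfinite(a) & np.isfinite(b)
            return np.corrcoef(a[ok], b[ok])[0, 1]

        assert lag_corr(1) > lag_corr(6) + 0.05

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            generate_cohort(_clean_spec(n_patients_per_class=(0, 5)))
        with pytest.raises(ParameterError):
            generate_cohort(_clean_spec(subclone_fraction=0.6))
        with pytest.raises(ParameterError):
            generate_cohort(_clean_spec(n_signal_features=41))
        with pytest.raises(ParameterError):
            generate_cohort(_clean_spec(mz_range=(3200.0, 600.0)))


class TestTransferCohort:
    def test_shared_and_independent_signal_sets(self):
        data, truth = generate_cohort(_clean_spec(spectra_per_patient=(20, 20)))
        spec_b = _clean_spec(seed=77, spectra_per_patient=(20, 20))
        _, t_shared = generate_transfer_cohort(spec_b, truth, shared_signal=True)
        assert np.array_equal(
            t_shared.signal_feature_indices, truth.signal_feature_indices
        )
        _, t_indep = generate_transfer_cohort(spec_b, truth, shared_signal=False)
        assert (
            len(set(t_indep.signal_feature_indices)
                & set(truth.signal_feature_indices)) == 0
        )
        assert np.array_equal(t_indep.feature_mzs, truth.feature_mzs)
        assert np.array_equal(t_indep.base_log_mean, truth.base_log_mean)
        assert np.array_equal(t_indep.healthy_shift, truth.healthy_shift)


class TestPeptideLibrary:
    def test_zero_jitter_masses_match_centroids(self):
        _, truth = generate_cohort(_clean_spec(spectra_per_patient=(5, 5)))
        lib = generate_peptide_library(
            truth, truth.feature_mzs, n_proteins=3, peptides_per_protein=2,
            mass_jitter_sd=0.0, seed=1,
        )
        ion_masses = lib["monoisotopic_mass"].to_numpy() + PROTON_MASS
        for m in ion_masses:
            assert np.min(np.abs(truth.feature_mzs - m)) < 1e-9

    def test_empty_library(self):
        _, truth = generate_cohort(_clean_spec(spectra_per_patient=(5, 5)))
        lib = generate_peptide_library(truth, truth.feature_mzs, n_proteins=0)
        assert len(lib) == 0

    def test_multi_peptide_proteins_use_colocalized_groups(self):
        _, truth = generate_cohort(_clean_spec(spectra_per_patient=(5, 5)))
        lib = generate_peptide_library(
            truth, truth.feature_mzs, n_proteins=2, peptides_per_protein=2, seed=4
        )
        groups = [set(g) for g in truth.signal_feature_groups if len(g) >= 2]
        for _, grp in lib.groupby("protein_id"):
            feats = {
                int(np.argmin(np.abs(truth.feature_mzs - (m + PROTON_MASS))))
                for m in grp["monoisotopic_mass"]
            }
            assert any(feats <= g for g in groups)

    def test_ground_truth_json_roundtrip(self, tmp_path):
        from msipredict.simulate import SyntheticGroundTruth

        _, truth = generate_cohort(_clean_spec(spectra_per_patient=(5, 5)))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SyntheticGroundTruth.from_json(path)
        assert np.array_equal(back.signal_feature_indices, truth.signal_feature_indices)
        assert np.allclose(back.feature_mzs, truth.feature_mzs)
        assert np.array_equal(back.subclone_mask, truth.subclone_mask)
        assert back.patient_outcomes.equals(truth.patient_outcomes)
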