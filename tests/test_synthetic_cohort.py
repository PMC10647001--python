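import numpy as np
import pandas as pd
import pytest

from als_proteome_state.containers import validate_metadata
from als_proteome_state.differential import progression_label
from als_proteome_state.synthetic_cohort import (
    CohortSpec,
    generate_alsfrsr_slopes,
    generate_cohort,
    read_cohort,
    signal_protein_ids,
    write_cohort,
)


class TestSlopes:
    def test_groups_by_construction(self):
        slopes = generate_alsfrsr_slopes(6, 5, seed=3)
        assert len(slopes) == 11
        labels = [progression_label(s) for s in slopes]
        assert labels.count("fast") == 6
        assert labels.count("slow") == 5

    def test_empty(self):
        assert generate_alsfrsr_slopes(0, 0, seed=1) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_alsfrsr_slopes(-1, 2, seed=0)


class TestGenerateCohort:
    def test_shape_and_labels(self):
        spec = CohortSpec(
            n_fast=6, n_slow=5, visits_per_patient=(4, 4), n_proteins=100, seed=7
        )
        matrix, metadata = generate_cohort(spec)
        assert matrix.n_proteins == 100
        assert matrix.n_samples == 44
        groups = metadata.drop_duplicates("patient_id")["alsfrsr_slope"].map(
            progression_label
        )
        assert (groups == "fast").sum() == 6
        assert (groups == "slow").sum() == 5

    def test_deterministic(self):
        spec = CohortSpec(n_proteins=60, seed=42)
        m1, md1 = generate_cohort(spec)
        m2, md2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(md1, md2)

    def test_no_missing_when_rate_zero(self):
        spec = CohortSpec(n_proteins=50, n_signal_proteins=5, missing_rate=0.0, seed=1)
        matrix, _ = generate_cohort(spec)
        assert not matrix.values.isna().any().any()

    def test_missing_fraction_matches_rate_uniform(self):
        spec = CohortSpec(
            n_fast=10, n_slow=10, n_proteins=500, missing_rate=0.2,
            missing_mnar_weight=0.0, seed=2,
        )
        matrix, _ = generate_cohort(spec)
        frac = matrix.values.isna().to_numpy().mean()
        assert abs(frac - 0.2) < 0.02

    def test_mnar_prefers_low_intensities(self):
        spec = CohortSpec(
            n_fast=8, n_slow=8, n_proteins=400, missing_rate=0.2,
            missing_mnar_weight=1.0, seed=3,
        )
        matrix, _ = generate_cohort(spec)
        observed = matrix.values.to_numpy()
        # proteins with low baselines should lose more entries
        frac = matrix.missing_fraction()
        means = matrix.values.mean(axis=1, skipna=True)
        assert np.corrcoef(means, frac)[0, 1] < -0.3

    def test_group_effect_recovered(self):
        spec = CohortSpec(
            n_fast=10, n_slow=10, visits_per_patient=(4, 4), n_proteins=120,
            n_signal_proteins=50, group_effect_log2=2.0,
            within_patient_sd_fast=0.2, within_patient_sd_slow=0.2,
            patient_random_effect_sd=0.2, batch_effect_sd=0.0,
            missing_rate=0.0, seed=4,
        )
        matrix, metadata = generate_cohort(spec)
        groups = metadata.set_index("sample_id")["patient_id"].str[0]
        fast_cols = groups[groups == "F"].index
        slow_cols = groups[groups == "S"].index
        diff = matrix.values[fast_cols].mean(axis=1) - matrix.values[slow_cols].mean(axis=1)
        sig = signal_protein_ids(spec)
        signs = np.where(np.arange(len(sig)) % 2 == 0, 1.0, -1.0)
        # per-protein SE of the mean difference; 3 SE tolerance on the average
        resid = diff[sig].to_numpy() - 2.0 * signs
        se = np.sqrt(2 * (0.2**2 + 0.2**2 / 40) / 10)
        assert np.abs(resid.mean()) < 3 * se / np.sqrt(len(sig))
        assert np.abs(diff[~diff.index.isin(sig)].mean()) < 3 * se

    def test_fast_group_noisier_within_patient(self):
        spec = CohortSpec(
            n_proteins=500, within_patient_sd_fast=0.6, within_patient_sd_slow=0.2,
            missing_rate=0.0, seed=5,
        )
        matrix, metadata = generate_cohort(spec)
        sds = {"F": [], "S": []}
        for pid, grp in metadata.groupby("patient_id"):
            vals = matrix.values[grp["sample_id"]]
            sds[pid[0]].append(vals.std(axis=1).median())
        assert np.median(sds["F"]) > np.median(sds["S"])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_fast=-1))
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(missing_rate=1.5))
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_signal_proteins=100, n_proteins=50))


class TestRoundTrip:
    def test_write_read_identity(self, small_cohort, tmp_path):
        _, matrix, metadata = small_cohort
        write_cohort(matrix, metadata, tmp_path)
        m2, md2 = read_cohort(tmp_path)
        assert np.allclose(
            matrix.values.to_numpy(), m2.values.to_numpy(), equal_nan=True
        )
        assert list(m2.protein_ids) == list(matrix.protein_ids)
        pd.testing.assert_frame_equal(
            metadata.reset_index(drop=True), md2, check_dtype=False
        )

    def test_missing_serialized_as_na(self, small_cohort, tmp_path):
        _, matrix, metadata = small_cohort
        write_cohort(matrix, metadata, tmp_path)
        text = (tmp_path / "abundance.tsv").read_text()
        assert "NA" in text
        m2, _ = read_cohort(tmp_path)
        assert m2.values.isna().sum().sum() == matrix.values.isna().sum().sum()

    def test_duplicate_sample_id_rejected(self, small_cohort, tmp_path):
        _, matrix, metadata = small_cohort
        bad = pd.concat([metadata, metadata.iloc[[0]]], ignore_index=True)
        write_cohort(matrix, bad, tmp_path)
        with pytest.raises(ValueError, match="duplicate sample_id"):
            read_cohort(tmp_path)

    def test_malformed_header_rejected(self, small_cohort, tmp_path):
        _, matrix, metadata = small_cohort
        write_cohort(matrix, metadata, tmp_path)
        f = tmp_path / "abundance.tsv"
        f.write_text(f.read_text().replace("protein_id", "protein", 1))
        with pytest.raises(ValueError, match="malformed"):
            read_cohort(tmp_path)


def test_metadata_invariants_enforced():
    md = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "patient_id": ["p", "p"],
            "visit_index": [1, 2],  # no baseline
            "months_from_baseline": [1.0, 2.0],
            "batch": ["B1", "B1"],
            "sex": ["M", "M"],
            "age_at_onset": [50, 50],
            "onset_site": ["Limb", "Limb"],
            "alsfrsr_slope": [1.2, 1.2],
        }
    )
    with pytest.raises(ValueError, match="baseline"):
        validate_metadata(md)
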