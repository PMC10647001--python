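"""Generate the synthetic discovery-like cohort used by the later stages.

The generator emulates the study design: 6 fast / 5 slow progressors, 3-5
visits at ~6-month spacing, ~1150 proteins with 59 carrying a stable
group-mean shift, higher visit-to-visit variance in fast progressors, two
batches, and intensity-dependent missingness. A second, larger cohort
(20 patients per group) is also written: at 6-vs-5 patients an exact rank
test cannot reach BH-adjusted p <= 0.0125, so the differential stage is
demonstrated at a size where the rule has power.
"""

from pathlib import Path

from als_proteome_state.synthetic_cohort import CohortSpec, generate_cohort, write_cohort

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
SEED = 1


def main() -> None:
    study = CohortSpec(seed=SEED)
    matrix, metadata = generate_cohort(study)
    write_cohort(matrix, metadata, SCRATCH / "cohort_study_scale")
    print(f"study-scale cohort: {matrix.n_proteins} proteins x {matrix.n_samples} samples, "
          f"{matrix.values.isna().to_numpy().mean():.1%} missing")

    powered = CohortSpec(
        n_fast=20, n_slow=20, visits_per_patient=(3, 3),
        n_signal_proteins=50, group_effect_log2=2.0,
        within_patient_sd_fast=0.4, within_patient_sd_slow=0.3,
        batch_count=2, batch_effect_sd=0.3, missing_rate=0.1, seed=SEED + 1,
    )
    matrix, metadata = generate_cohort(powered)
    write_cohort(matrix, metadata, SCRATCH / "cohort_powered")
    print(f"powered cohort: {matrix.n_proteins} proteins x {matrix.n_samples} samples")


if __name__ == "__main__":
    main()
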