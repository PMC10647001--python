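"""Seeded synthetic longitudinal CSF-proteomics cohorts.

Generates protein × sample log2 abundance matrices with the statistical
structure the downstream analyses assume: a discovery-sized two-group cohort
(fast vs slow progressors), a subset of "signal" proteins whose group-mean
shift is constant over time (near-zero slopes), greater visit-to-visit
within-patient variance in fast progressors, additive batch structure, and
intensity-dependent (MNAR-leaning) missingness typical of label-free
quantitation.

The generative model for entry (protein p, sample s of patient i at visit v):

    y_ps = b_p + d_p * 1[i is fast] + a_ip + g_{p,batch(s)} + e_ps

with protein baseline b_p ~ N(20, 2^2) (log2 LFQ-like), signed group effect
d_p (zero for null proteins), patient random effect a_ip, batch effect
g_{p,batch} drawn once per cohort, and visit noise e_ps whose SD depends on
the patient's progression group. Fast/slow labels are never stored: they are
derived from the generated ALSFRS-R slopes via
:func:`als_proteome_state.differential.progression_label`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, METADATA_COLUMNS, validate_metadata

# ALSFRS-R slope ranges (units/month) bracketing the observed cohort:
# fast progressors 1.00-2.67, slow 0.00-0.48.
FAST_SLOPE_RANGE = (1.0, 2.7)
SLOW_SLOPE_RANGE = (0.0, 0.48)

BASELINE_MEAN = 20.0
BASELINE_SD = 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic longitudinal cohort.

    Defaults mirror the discovery-cohort design: 6 fast / 5 slow progressors,
    3-5 visits at roughly 6-month spacing, ~1150 proteins of which 59 carry a
    stable group-mean shift, and larger visit-to-visit proteome noise in fast
    progressors.
    """

    n_fast: int = 6
    n_slow: int = 5
    visits_per_patient: tuple[int, int] = (3, 5)
    visit_spacing_months: float = 6.0
    n_proteins: int = 1150
    n_signal_proteins: int = 59
    group_effect_log2: float = 1.0
    within_patient_sd_fast: float = 0.6
    within_patient_sd_slow: float = 0.2
    patient_random_effect_sd: float = 0.3
    batch_count: int = 2
    batch_effect_sd: float = 0.3
    missing_rate: float = 0.1
    missing_mnar_weight: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_fast < 0 or self.n_slow < 0:
            raise ValueError("patient counts must be nonnegative")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not 0 <= self.n_signal_proteins <= self.n_proteins:
            raise ValueError("n_signal_proteins must be in [0, n_proteins]")
        lo, hi = self.visits_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_patient must be a nondecreasing positive range")
        if self.visit_spacing_months <= 0:
            raise ValueError("visit_spacing_months must be positive")
        for name in ("within_patient_sd_fast", "within_patient_sd_slow", "patient_random_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be nonnegative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.missing_mnar_weight <= 1.0:
            raise ValueError("missing_mnar_weight must be in [0, 1]")


def generate_alsfrsr_slopes(n_fast: int, n_slow: int, seed: int | np.random.Generator) -> list[float]:
    """Draw ALSFRS-R decline rates (units/month) for a two-group cohort.

    Fast-progressor slopes are uniform on [1.0, 2.7] and slow on [0.0, 0.48],
    so every fast slope is >= 1 and every slow slope < 0.5 by construction.
    Fast slopes come first in the returned list.
    """
    if n_fast < 0 or n_slow < 0:
        raise ValueError("counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fast = rng.uniform(*FAST_SLOPE_RANGE, size=n_fast)
    slow = rng.uniform(*SLOW_SLOPE_RANGE, size=n_slow)
    return [float(x) for x in np.concatenate([fast, slow])]


def _signal_effects(spec: CohortSpec) -> np.ndarray:
    """Signed per-protein group effects: zero for nulls, alternating-sign
    shifts of magnitude ``group_effect_log2`` for the signal proteins."""
    d = np.zeros(spec.n_proteins)
    signs = np.where(np.arange(spec.n_signal_proteins) % 2 == 0, 1.0, -1.0)
    d[: spec.n_signal_proteins] = signs * spec.group_effect_log2
    return d


def signal_protein_ids(spec: CohortSpec) -> list[str]:
    """IDs of the proteins carrying a planted group effect."""
    return [f"SIG{i + 1:04d}" for i in range(spec.n_signal_proteins)]


def _protein_ids(spec: CohortSpec) -> list[str]:
    n_null = spec.n_proteins - spec.n_signal_proteins
    return signal_protein_ids(spec) + [f"PROT{i + 1:04d}" for i in range(n_null)]


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Generate a synthetic cohort: (log2 abundance matrix, sample metadata).

    Identical spec + seed yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    slopes = generate_alsfrsr_slopes(spec.n_fast, spec.n_slow, rng)
    patient_ids = [f"F{i + 1}" for i in range(spec.n_fast)] + [
        f"S{i + 1}" for i in range(spec.n_slow)
    ]
    is_fast = [True] * spec.n_fast + [False] * spec.n_slow

    lo, hi = spec.visits_per_patient
    meta_rows = []
    for pid, fast, slope in zip(patient_ids, is_fast, slopes):
        n_visits = int(rng.integers(lo, hi + 1))
        gaps = spec.visit_spacing_months * rng.uniform(0.5, 1.5, size=n_visits - 1)
        months = np.concatenate([[0.0], np.cumsum(gaps)])
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(np.clip(rng.normal(52.0, 11.0), 25, 80))
        site = "Limb" if rng.random() < 0.8 else "Bulbar"
        for v in range(n_visits):
            meta_rows.append(
                {
                    "sample_id": f"{pid}_V{v}",
                    "patient_id": pid,
                    "visit_index": v,
                    "months_from_baseline": round(float(months[v]), 3),
                    "batch": "",  # assigned below
                    "sex": sex,
                    "age_at_onset": round(age, 1),
                    "onset_site": site,
                    "alsfrsr_slope": round(slope, 3),
                }
            )
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    n_samples = len(metadata)

    # balanced, shuffled batch assignment
    batches = np.array([f"B{i % spec.batch_count + 1}" for i in range(n_samples)])
    rng.shuffle(batches)
    metadata["batch"] = batches

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=spec.n_proteins)
    effects = _signal_effects(spec)
    batch_labels = [f"B{i + 1}" for i in range(spec.batch_count)]
    batch_fx = {
        b: rng.normal(0.0, spec.batch_effect_sd, size=spec.n_proteins) for b in batch_labels
    }
    patient_fx = {
        pid: rng.normal(0.0, spec.patient_random_effect_sd, size=spec.n_proteins)
        for pid in patient_ids
    }

    fast_by_pid = dict(zip(patient_ids, is_fast))
    cols = {}
    for row in metadata.itertuples(index=False):
        fast = fast_by_pid[row.patient_id]
        sd = spec.within_patient_sd_fast if fast else spec.within_patient_sd_slow
        y = (
            baseline
            + (effects if fast else 0.0)
            + patient_fx[row.patient_id]
            + batch_fx[row.batch]
            + rng.normal(0.0, sd, size=spec.n_proteins)
        )
        cols[row.sample_id] = y
    values = pd.DataFrame(cols, index=_protein_ids(spec))

    if spec.missing_rate > 0:
        values = _apply_missingness(values, spec, rng)

    matrix = AbundanceMatrix(values=values, scale="log2")
    return matrix, validate_metadata(metadata)


def _apply_missingness(
    values: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Blend of uniform and intensity-ranked (MNAR) dropout.

    Entry dropout probability is ``(1-w)*r + w*r*g`` where g decreases
    linearly from 2 (lowest intensity) to 0 (highest); g has mean 1 so the
    expected overall missing fraction is r regardless of w.
    """
    r, w = spec.missing_rate, spec.missing_mnar_weight
    flat = values.to_numpy().ravel()
    order = flat.argsort().argsort()  # rank 0 = lowest intensity
    rank_frac = order / max(len(flat) - 1, 1)
    g = 2.0 * (1.0 - rank_frac)
    p = np.clip((1.0 - w) * r + w * r * g, 0.0, 1.0)
    drop = rng.random(size=flat.shape) < p
    out = flat.copy()
    out[drop] = np.nan
    return pd.DataFrame(out.reshape(values.shape), index=values.index, columns=values.columns)


def write_cohort(matrix: AbundanceMatrix, metadata: pd.DataFrame, directory: str | Path) -> None:
    """Write ``abundance.tsv`` and ``metadata.tsv`` (missing values as NA)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ab = matrix.values.copy()
    ab.index.name = "protein_id"
    ab.to_csv(directory / "abundance.tsv", sep="\t", na_rep="NA", float_format="%.10g")
    metadata.to_csv(directory / "metadata.tsv", sep="\t", index=False, na_rep="NA")
    (directory / "scale.txt").write_text(matrix.scale + "\n")


def read_cohort(directory: str | Path) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; round-trip is lossless."""
    directory = Path(directory)
    ab = pd.read_csv(directory / "abundance.tsv", sep="\t", na_values=["NA"])
    if ab.columns[0] != "protein_id":
        raise ValueError(
            f"malformed abundance header: first column {ab.columns[0]!r}, expected 'protein_id'"
        )
    ab = ab.set_index("protein_id")
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t", na_values=["NA"])
    scale_file = directory / "scale.txt"
    scale = scale_file.read_text().strip() if scale_file.exists() else "log2"
    matrix = AbundanceMatrix(values=ab, scale=scale)
    return matrix, validate_metadata(metadata)
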