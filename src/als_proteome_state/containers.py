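"""Core in-memory containers shared across the pipeline.

The central object is :class:`AbundanceMatrix` — a proteins × samples matrix of
log-scale label-free quantitation (LFQ) intensities with missing entries — and
the per-sample metadata table that carries patient, visit, batch and clinical
annotations. Both wrap pandas objects so downstream code can lean on pandas
alignment and IO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Allowed scale states, in the only order transitions may occur.
SCALES = ("raw", "log2", "normalized")

#: Metadata columns every sample table must carry.
METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "visit_index",
    "months_from_baseline",
    "batch",
    "sex",
    "age_at_onset",
    "onset_site",
    "alsfrsr_slope",
)


@dataclass
class AbundanceMatrix:
    """Proteins × samples abundance matrix with missing entries allowed.

    Parameters
    ----------
    values
        DataFrame indexed by protein ID with one column per sample ID.
        Missing measurements are NaN.
    scale
        One of ``raw``, ``log2``, ``normalized``. Scale may only move
        forward along that sequence (raw → log2 → normalized).
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein IDs: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-protein fraction of missing entries."""
        return self.values.isna().mean(axis=1)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values=values, scale=scale or self.scale)

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        return self.with_values(self.values.loc[list(protein_ids)])

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return self.with_values(self.values[list(sample_ids)])


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it sorted by patient/visit.

    Enforces: required columns present, unique sample IDs, a baseline visit
    (index 0) for every patient, and months strictly increasing with visit
    index within each patient.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id: {dupes}")
    out = metadata.sort_values(["patient_id", "visit_index"]).reset_index(drop=True)
    for pid, grp in out.groupby("patient_id"):
        if grp["visit_index"].min() != 0:
            raise ValueError(f"patient {pid} has no baseline visit (visit_index 0)")
        months = grp["months_from_baseline"].to_numpy()
        if not np.all(np.diff(months) > 0):
            raise ValueError(f"patient {pid}: months_from_baseline not strictly increasing")
    return out


def first_last_visits(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-patient sample IDs at the first (baseline) and last visit."""
    rows = []
    for pid, grp in metadata.groupby("patient_id"):
        grp = grp.sort_values("visit_index")
        rows.append(
            {
                "patient_id": pid,
                "first_sample": grp.iloc[0]["sample_id"],
                "last_sample": grp.iloc[-1]["sample_id"],
            }
        )
    return pd.DataFrame(rows)
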