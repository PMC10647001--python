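"""Normalization, batch adjustment and missingness filtering.

The normalization here is a transparent variance-stabilizing stand-in:
log2(x+1) (when the matrix is still on the raw scale) followed by per-sample
median calibration, which equalises sample medians exactly while preserving
within-sample rank order. Batch adjustment removes per-protein batch means
and restores the protein grand mean. Missing values are left missing — all
downstream tests drop them pairwise; no imputation is performed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix


def vst_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Variance-stabilizing normalization by per-sample median calibration.

    Raw-scale input is first mapped through log2(x+1). Each sample column is
    then shifted so its median equals the grand median of per-sample medians.
    Idempotent on its own output.
    """
    if matrix.scale == "normalized":
        values = matrix.values.copy()
    elif matrix.scale == "raw":
        values = np.log2(matrix.values + 1.0)
    else:
        values = matrix.values.copy()

    if values.isna().all(axis=0).any():
        bad = values.columns[values.isna().all(axis=0)].tolist()
        raise ValueError(f"samples with all values missing: {bad}")

    medians = values.median(axis=0, skipna=True)
    target = medians.median()
    values = values - (medians - target)
    return matrix.with_values(values, scale="normalized")


def batch_adjust(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> AbundanceMatrix:
    """Remove additive per-protein batch effects, restoring protein grand means.

    For each protein the per-batch mean (over observed entries) is subtracted
    and the protein's grand mean added back, so per-protein batch means are
    equalised while grand means are unchanged. Batches with a single sample
    are passed through with a warning (their offset is not identifiable).
    """
    batch_of = metadata.set_index("sample_id")["batch"]
    missing = [s for s in matrix.sample_ids if s not in batch_of.index]
    if missing:
        raise ValueError(f"samples without batch labels: {missing}")
    batches = batch_of.loc[matrix.sample_ids]

    values = matrix.values.copy()
    counts = batches.value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(
            f"singleton batches passed through unadjusted: {singletons}", stacklevel=2
        )

    adjusted_cols = [s for s in matrix.sample_ids if counts[batches[s]] >= 2]
    if not adjusted_cols:
        return matrix.with_values(values)

    sub = values[adjusted_cols]
    grand = sub.mean(axis=1, skipna=True)
    for b in counts[counts >= 2].index:
        cols = [s for s in adjusted_cols if batches[s] == b]
        bmean = values[cols].mean(axis=1, skipna=True)
        values[cols] = values[cols].sub(bmean - grand, axis=0)
    return matrix.with_values(values)


def filter_proteins(matrix: AbundanceMatrix, max_missing_frac: float) -> AbundanceMatrix:
    """Drop proteins whose missing fraction exceeds the threshold.

    Protein order is preserved.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    keep = matrix.missing_fraction() <= max_missing_frac
    return matrix.with_values(matrix.values.loc[keep])


def impute_protein_means(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing entries with the protein's mean over observed samples.

    Only used by consumers that require a complete matrix (PCA projection);
    statistical tests drop missing values pairwise instead.
    """
    values = matrix.values.copy()
    means = values.mean(axis=1, skipna=True)
    values = values.apply(lambda col: col.fillna(means))
    if values.isna().any().any():
        raise ValueError("proteins with no observed values cannot be imputed")
    return matrix.with_values(values)
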