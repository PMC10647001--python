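"""Cross-sectional differential abundance between fast and slow progressors.

The candidate-panel construction compares the two progression groups four
ways — fast vs slow at the first visit, at the last visit, and the two
crossed first/last combinations — with a Mann-Whitney test per protein,
Benjamini-Hochberg adjustment across proteins, and a joint fold-change +
adjusted-p significance rule. The panel is the intersection of the four
significant sets with a consistent direction of change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, first_last_visits
from .ranktests import mann_whitney_p

#: ALSFRS-R decline thresholds (units/month) defining the progression groups.
FAST_SLOPE_MIN = 1.0
SLOW_SLOPE_MAX = 0.5  # exclusive

#: Default significance rule: fold change >= 1.5 and BH-adjusted p <= 0.0125.
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.0125

#: The four cross-sectional comparisons, as (fast visit, slow visit).
FOUR_WAY_COMPARISONS = {
    "fast_first_vs_slow_first": ("first", "first"),
    "fast_last_vs_slow_last": ("last", "last"),
    "fast_first_vs_slow_last": ("first", "last"),
    "fast_last_vs_slow_first": ("last", "first"),
}


def progression_label(alsfrsr_slope: float) -> str:
    """Classify an ALSFRS-R decline rate: 'fast' (>= 1 unit/month),
    'slow' (< 0.5), or 'intermediate' (excluded from all analyses)."""
    if alsfrsr_slope is None or (isinstance(alsfrsr_slope, float) and math.isnan(alsfrsr_slope)):
        raise ValueError("missing ALSFRS-R slope; cannot assign progression group")
    if alsfrsr_slope < 0:
        raise ValueError(f"negative ALSFRS-R decline rate: {alsfrsr_slope}")
    if alsfrsr_slope >= FAST_SLOPE_MIN:
        return "fast"
    if alsfrsr_slope < SLOW_SLOPE_MAX:
        return "slow"
    return "intermediate"


def patient_groups(metadata: pd.DataFrame) -> pd.Series:
    """Per-patient progression group derived from the ALSFRS-R slope."""
    per_patient = metadata.drop_duplicates("patient_id").set_index("patient_id")
    return per_patient["alsfrsr_slope"].map(progression_label)


def sample_groups(metadata: pd.DataFrame) -> pd.Series:
    """Per-sample progression group ('fast'/'slow'/'intermediate')."""
    groups = patient_groups(metadata)
    return metadata.set_index("sample_id")["patient_id"].map(groups)


def mann_whitney_bh(
    matrix: AbundanceMatrix,
    samples_a: list[str],
    samples_b: list[str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-protein Mann-Whitney differential abundance, group A minus group B.

    Missing values are dropped pairwise; proteins with fewer than two
    observations in either group are flagged untestable and excluded from the
    BH family. Returns a DataFrame with columns protein_id, log2_fc, p_raw,
    p_adj, significant, direction, untestable.

    ``log2_fc`` is the difference of group means on the log2 scale, so the
    significance rule |log2_fc| >= log2(fc_threshold) matches a fold-change
    threshold on the raw scale.
    """
    va = matrix.values[samples_a].to_numpy()
    vb = matrix.values[samples_b].to_numpy()
    n_prot = matrix.n_proteins

    log2_fc = np.full(n_prot, np.nan)
    p_raw = np.full(n_prot, np.nan)
    untestable = np.zeros(n_prot, dtype=bool)
    for i in range(n_prot):
        a = va[i][~np.isnan(va[i])]
        b = vb[i][~np.isnan(vb[i])]
        if a.size < 2 or b.size < 2:
            untestable[i] = True
            continue
        log2_fc[i] = a.mean() - b.mean()
        p_raw[i] = mann_whitney_p(a, b)

    p_adj = np.full(n_prot, np.nan)
    tested = ~untestable
    if tested.any():
        p_adj[tested] = multipletests(p_raw[tested], method="fdr_bh")[1]

    significant = (
        tested
        & (np.abs(log2_fc) >= np.log2(fc_threshold) - 1e-12)
        & (p_adj <= alpha + 1e-12)
    )
    direction = np.where(log2_fc >= 0, "up_in_FP", "up_in_SP")
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "log2_fc": log2_fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
            "direction": direction,
            "untestable": untestable,
        }
    )


def _cross_section_samples(metadata: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Sample IDs per (group, first/last visit) cell, intermediates excluded."""
    groups = patient_groups(metadata)
    fl = first_last_visits(metadata).set_index("patient_id")
    cells: dict[tuple[str, str], list[str]] = {
        (g, v): [] for g in ("fast", "slow") for v in ("first", "last")
    }
    for pid, grp in groups.items():
        if grp == "intermediate":
            continue
        cells[(grp, "first")].append(fl.loc[pid, "first_sample"])
        cells[(grp, "last")].append(fl.loc[pid, "last_sample"])
    return cells


def four_way_panel(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    require_direction: bool = True,
) -> tuple[list[str], dict[str, pd.DataFrame]]:
    """Run the four fast-vs-slow cross sections and intersect the hits.

    Returns the candidate panel (protein IDs significant in all four
    comparisons, with a consistent direction of change when
    ``require_direction``) and the per-comparison result tables.
    """
    cells = _cross_section_samples(metadata)
    results: dict[str, pd.DataFrame] = {}
    for name, (visit_fast, visit_slow) in FOUR_WAY_COMPARISONS.items():
        results[name] = mann_whitney_bh(
            matrix,
            cells[("fast", visit_fast)],
            cells[("slow", visit_slow)],
            fc_threshold=fc_threshold,
            alpha=alpha,
        )

    panel: list[str] = []
    tables = {name: res.set_index("protein_id") for name, res in results.items()}
    for pid in matrix.protein_ids:
        rows = [tables[name].loc[pid] for name in FOUR_WAY_COMPARISONS]
        if not all(r["significant"] for r in rows):
            continue
        if require_direction and len({r["direction"] for r in rows}) > 1:
            continue
        panel.append(pid)
    return panel, results
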