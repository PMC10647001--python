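"""Published patient-level demographics of the two longitudinal CSF cohorts.

The study enrolled 22 ALS patients sampled over three or more clinic visits,
split into a discovery cohort (11 patients) and an independent validation
cohort (11 patients). Each record carries the number of visits, the months
elapsed between baseline and last visit, sex, age at symptom onset (years;
missing for one validation patient), age at first CSF draw, the monthly rate
of ALSFRS-R decline, and the site of symptom onset. Progression labels
(fast ≥ 1 ALSFRS-R unit/month, slow < 0.5) are *derived* from the slopes by
:func:`als_proteome_state.differential.progression_label`, never stored.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "code",
    "n_visits",
    "months_span",
    "sex",
    "age_at_onset",
    "age_at_first_visit",
    "alsfrsr_slope",
    "onset_site",
]

_DISCOVERY = [
    ("S1", 4, 28, "F", 43, 46, 0.32, "Limb"),
    ("S2", 4, 24, "M", 53, 57, 0.29, "Limb"),
    ("S3", 4, 20, "F", 31, 65, 0.21, "Bulbar"),
    ("S4", 4, 18, "M", 56, 57, 0.00, "Limb"),
    ("S5", 3, 6, "F", 34, 36, 0.28, "Limb"),
    ("F1", 4, 13, "M", 56, 57, 1.69, "Bulbar"),
    ("F2", 4, 12, "F", 65, 67, 1.66, "Limb"),
    ("F3", 3, 8, "M", 54, 55, 1.50, "Limb"),
    ("F4", 5, 35, "F", 59, 59, 1.00, "Limb"),
    ("F5", 4, 21, "M", 52, 53, 2.33, "Limb"),
    ("F6", 4, 20, "M", 40, 41, 2.67, "Limb"),
]

_VALIDATION = [
    ("S6", 3, 12, "F", 58, 65, 0.03, "Limb"),
    ("S7", 3, 8, "M", 38, 41, 0.07, "Limb"),
    ("S8", 3, 11, "F", 64, 66, 0.48, "Bulbar"),
    ("S9", 3, 8, "F", 27, 43, 0.03, "Limb"),
    ("S10", 3, 9, "M", 46, 54, 0.17, "Limb"),
    ("S11", 3, 9, "M", 63, 66, 0.12, "Limb"),
    ("F7", 3, 8, "M", None, 51, 1.50, "Limb"),
    ("F8", 3, 7, "F", 52, 53, 1.37, "Limb"),
    ("F9", 3, 6, "M", 54, 55, 2.67, "Limb"),
    ("F10", 3, 8, "F", 58, 59, 2.34, "Limb"),
    ("F11", 3, 8, "M", 75, 77, 1.05, "Limb"),
]


def discovery_cohort() -> pd.DataFrame:
    """Demographics of the 11-patient discovery cohort."""
    return pd.DataFrame(_DISCOVERY, columns=_COLUMNS)


def validation_cohort() -> pd.DataFrame:
    """Demographics of the 11-patient validation cohort."""
    return pd.DataFrame(_VALIDATION, columns=_COLUMNS)
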