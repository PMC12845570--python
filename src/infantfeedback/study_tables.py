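"""Bundled reference cohort tables.

Twelve infants at high risk of cerebral palsy who took part in a six-month
home-based feedback-training pilot.  The training journal records achieved
dose (days and hours trained over the intervention); the clinical table
records corrected age at intervention start, the dominant hand as scored by
a standardized hand assessment (``L``/``R``/``none``; ``NA`` where the test
could not be administered), and the Alberta Infant Motor Scale score.

These tables drive the compliance analytics and serve as small real-data
fixtures for the statistics; the sensor recordings themselves are not
publicly deposited, so movement-level analyses run on synthetic sessions.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["training_journal", "clinical_scores"]

_JOURNAL = [
    # (infant_id, days_trained, hours_trained)
    (1, 93, 22.6),
    (2, 57, 12.1),
    (3, 0, 0.0),
    (5, 81, 19.0),
    (7, 57, 8.6),
    (8, 0, 0.0),
    (9, 93, 22.2),
    (10, 8, 1.7),
    (11, 23, 5.1),
    (12, 88, 21.2),
    (13, 54, 12.3),
    (14, 0, 0.0),
]

_CLINICAL = [
    # (infant_id, corrected_age_weeks, dominant_hand, aims)
    (1, 18, "R", 9),
    (2, 23, "L", 20),
    (3, 20, "NA", 14),
    (5, 18, "none", 6),
    (7, 17, "NA", 9),
    (8, 14, "NA", 8),
    (9, 32, "NA", 10),
    (10, 17, "L", 17),
    (11, 14, "L", 11),
    (12, 21, "R", 11),
    (13, 14, "R", 9),
    (14, 22, "R", 27),
]


def training_journal() -> pd.DataFrame:
    """Per-infant achieved training dose (days and hours over the pilot)."""
    return pd.DataFrame(_JOURNAL, columns=["infant_id", "days_trained", "hours_trained"])


def clinical_scores() -> pd.DataFrame:
    """Per-infant clinical profile: corrected age, dominant hand, AIMS."""
    return pd.DataFrame(
        _CLINICAL, columns=["infant_id", "corrected_age_weeks", "dominant_hand", "aims"]
    )
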