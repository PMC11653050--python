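"""Reference demographic table of the target cohort.

The pipeline targets the 16-participant glycemic-variability wearable
accession (men and postmenopausal women with HbA1c in the high-normal to
prediabetic band, monitored for 8–10 days with a 5-min CGM and a wrist
wearable). The published demographic table is embedded here so cohort-level
summaries can be computed without the accession itself.
"""

from __future__ import annotations

import numpy as np

from glycowear.datatypes import ParticipantRecord

#: (id, sex, HbA1c %) for the 16 participants of the reference cohort.
REFERENCE_DEMOGRAPHICS: tuple[tuple[str, str, float], ...] = (
    ("a01", "female", 5.5),
    ("a02", "male", 5.6),
    ("a03", "female", 5.9),
    ("a04", "female", 6.4),
    ("a05", "female", 5.7),
    ("a06", "female", 5.8),
    ("a07", "female", 5.3),
    ("a08", "female", 5.6),
    ("a09", "male", 6.1),
    ("a10", "female", 6.0),
    ("a11", "male", 6.0),
    ("a12", "male", 5.6),
    ("a13", "male", 5.7),
    ("a14", "male", 5.5),
    ("a15", "female", 5.5),
    ("a16", "male", 5.5),
)


def reference_participants() -> list[ParticipantRecord]:
    """The reference cohort as validated participant records."""
    return [ParticipantRecord(pid, sex, h) for pid, sex, h in REFERENCE_DEMOGRAPHICS]


def cohort_summary(participants: list[ParticipantRecord]) -> dict[str, float]:
    """Cohort-level demographics: HbA1c mean/SD (sample SD) and male fraction."""
    hba1c = np.array([p.hba1c for p in participants])
    males = sum(p.sex == "male" for p in participants)
    return {
        "n": len(participants),
        "hba1c_mean": float(hba1c.mean()),
        "hba1c_sd": float(hba1c.std(ddof=1)),
        "male_fraction": males / len(participants),
    }
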