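"""Shared vocabulary: boxes, dispositions, status flags, column schemas.

Event tables are plain pandas DataFrames with the column contracts listed
here; small enums carry the categorical vocabulary.  Dates are datetime64
columns in memory and ISO 8601 (YYYY-MM-DD) strings on disk.
"""

from __future__ import annotations

import enum

__all__ = [
    "Box",
    "Disposition",
    "FLAG_DISPOSITIONS",
    "FLAG_FOR_DISPOSITION",
    "DISPOSITION_ORDER",
    "STATUS_FLAGS",
    "VL_UNDETECTABLE_MAX",
    "CD4_BINS",
    "SEX_LEVELS",
    "RACE_LEVELS",
    "EXPOSURE_LEVELS",
    "AGE_GROUP_LEVELS",
    "PATIENT_COLUMNS",
    "VISIT_COLUMNS",
    "APPOINTMENT_COLUMNS",
    "LAB_COLUMNS",
]


class Box(str, enum.Enum):
    """Joint visit/VL presence in the OOC window.

    A: visit and VL (still in care, excluded); B: VL only; C: visit only;
    D: neither.  B/C/D together are the "potentially out of care" cohort.
    """

    A = "A"
    B = "B"
    C = "C"
    D = "D"


class Disposition(str, enum.Enum):
    """Case-conference outcome, listed in stepwise precedence order.

    The engine evaluates rules top to bottom and stops at the first that
    fires; a patient reaching the bottom is randomizable.
    """

    WELL_PATIENT = "WELL_PATIENT"
    RECENT_VISIT = "RECENT_VISIT"
    UPCOMING_VISIT = "UPCOMING_VISIT"
    EXTENDED_CARE_FACILITY = "EXTENDED_CARE_FACILITY"
    INCARCERATED = "INCARCERATED"
    MOVED_OUT_OF_STATE = "MOVED_OUT_OF_STATE"
    NOT_OUR_PATIENT = "NOT_OUR_PATIENT"
    DECEASED = "DECEASED"
    PROVIDER_DISCRETION = "PROVIDER_DISCRETION"
    OTHER = "OTHER"
    RANDOMIZABLE = "RANDOMIZABLE"


DISPOSITION_ORDER: list[Disposition] = list(Disposition)

#: Dispositions (4)-(10): driven by status flags / clinic annotations.
FLAG_DISPOSITIONS: list[Disposition] = [
    Disposition.EXTENDED_CARE_FACILITY,
    Disposition.INCARCERATED,
    Disposition.MOVED_OUT_OF_STATE,
    Disposition.NOT_OUR_PATIENT,
    Disposition.DECEASED,
    Disposition.PROVIDER_DISCRETION,
    Disposition.OTHER,
]

#: status-flag column backing each flag disposition, in precedence order.
FLAG_FOR_DISPOSITION: dict[Disposition, str] = {
    Disposition.EXTENDED_CARE_FACILITY: "extended_care_facility",
    Disposition.INCARCERATED: "incarcerated",
    Disposition.MOVED_OUT_OF_STATE: "moved_out_of_state",
    Disposition.NOT_OUR_PATIENT: "transferred_out",
    Disposition.DECEASED: "deceased",
    Disposition.PROVIDER_DISCRETION: "provider_discretion",
    Disposition.OTHER: "other_flag",
}

STATUS_FLAGS: list[str] = list(FLAG_FOR_DISPOSITION.values())

#: copies/ml at or below which a viral load is undetectable.
VL_UNDETECTABLE_MAX: float = 20.0

#: CD4 bin labels (cells/µl), lowest first.
CD4_BINS: list[str] = ["<200", "200-299", "300-499", ">=500"]

SEX_LEVELS = ["male", "female"]
RACE_LEVELS = ["Hispanic", "Black_not_Hispanic", "White_not_Hispanic", "Other"]
EXPOSURE_LEVELS = [
    "MSM",
    "IDU",
    "heterosexual_only",
    "MSM_and_IDU",
    "other",
    "none_identified",
]
AGE_GROUP_LEVELS = ["under_30", "30-39", "40-49", "50-59", "over_60"]

PATIENT_COLUMNS = (
    ["patient_id", "birth_date", "sex_at_birth", "race_ethnicity",
     "exposure_category", "clinic_id"] + STATUS_FLAGS
)
VISIT_COLUMNS = ["patient_id", "clinic_id", "visit_date"]
APPOINTMENT_COLUMNS = ["patient_id", "clinic_id", "scheduled_date", "kept"]
LAB_COLUMNS = ["patient_id", "test_date", "kind", "value"]
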