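"""Revised HIV care-continuum estimation.

Surveillance-based continuum reports count everyone without recent labs as
out of care.  Reconciliation shows that a large fraction of those
"potentially OOC" are actually in care (well patients, recent or upcoming
visits, moved, deceased, ...).  This module propagates that fraction back
into the continuum:

    additional_in_care = round(nonrandomizable_frac * potentially_ooc)
    revised_retained   = retained + additional_in_care
    truly_ooc          = prevalent - revised_retained

and attributes the additional in-care cases to Box B/C/D via the box
composition of the non-randomized group.  Counts round half-up to integers,
percentages half-up to one decimal of the prevalent count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .rounding import pct, round_half_up
from .window import StudyWindow

__all__ = [
    "ContinuumInputs",
    "ContinuumEstimate",
    "revise_continuum",
    "nonrandomizable_fraction",
    "retained_by_surveillance",
]

_BOXES = ("B", "C", "D")


@dataclass(frozen=True)
class ContinuumInputs:
    """Inputs to the continuum revision.

    prevalent / retained are the surveillance continuum's diagnosed and
    retained-in-care counts; potentially_ooc defaults to their difference.
    nonrandomizable_frac is the proportion of the potentially-OOC cohort the
    reconciliation found to be not randomizable (i.e. actually in care or
    otherwise not reachable for the trial); box_shares_nonrandomized is the
    Box B/C/D composition of that non-randomized group.
    """

    prevalent: int
    retained: int
    nonrandomizable_frac: float
    box_shares_nonrandomized: tuple[float, float, float]
    potentially_ooc: int | None = None

    def __post_init__(self) -> None:
        if self.retained > self.prevalent:
            raise ValueError("retained cannot exceed prevalent")
        if not 0.0 <= self.nonrandomizable_frac <= 1.0:
            raise ValueError(
                f"nonrandomizable_frac must be in [0, 1], got {self.nonrandomizable_frac}"
            )
        total = sum(self.box_shares_nonrandomized)
        # printed shares carry rounding error (e.g. 27.8+48.4+23.9 = 100.1)
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"box shares must sum to 1 within ±0.005, got {total}")
        if self.potentially_ooc is None:
            object.__setattr__(self, "potentially_ooc", self.prevalent - self.retained)


@dataclass(frozen=True)
class ContinuumEstimate:
    additional_in_care: int
    revised_retained: int
    truly_ooc: int
    revised_retained_pct: float
    truly_ooc_pct: float
    box_attribution: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "additional_in_care": self.additional_in_care,
            "revised_retained": self.revised_retained,
            "truly_ooc": self.truly_ooc,
            "revised_retained_pct": self.revised_retained_pct,
            "truly_ooc_pct": self.truly_ooc_pct,
        }
        for box, v in self.box_attribution.items():
            d[f"box_{box}_additional"] = v["count"]
            d[f"box_{box}_pct_of_prevalent"] = v["pct_of_prevalent"]
        return d


def revise_continuum(inputs: ContinuumInputs) -> ContinuumEstimate:
    """Fold the non-randomizable fraction back into the retention estimate."""
    additional = int(round_half_up(inputs.nonrandomizable_frac * inputs.potentially_ooc))
    revised_retained = inputs.retained + additional
    truly_ooc = inputs.prevalent - revised_retained
    attribution = {}
    for box, share in zip(_BOXES, inputs.box_shares_nonrandomized):
        count = int(round_half_up(additional * share))
        attribution[box] = {
            "count": count,
            "pct_of_prevalent": pct(count, inputs.prevalent),
        }
    return ContinuumEstimate(
        additional_in_care=additional,
        revised_retained=revised_retained,
        truly_ooc=truly_ooc,
        revised_retained_pct=pct(revised_retained, inputs.prevalent),
        truly_ooc_pct=pct(truly_ooc, inputs.prevalent),
        box_attribution=attribution,
    )


def nonrandomizable_fraction(n_nonrandomized: int, n_potentially_ooc: int) -> float:
    """Non-randomizable proportion at the precision the continuum uses.

    Rounded half-up to one decimal of a percent (2,303/2,958 -> 0.779), so a
    fraction computed from a pipeline run and one quoted from a report
    feed the revision identically.
    """
    return pct(n_nonrandomized, n_potentially_ooc) / 100.0


def retained_by_surveillance(labs: pd.DataFrame, window: StudyWindow) -> pd.Series:
    """Surveillance retention: ≥2 VLs at least 3 calendar months apart in the in-care year.

    Convenience helper mirroring the statewide continuum's retention
    definition on a lab stream; the continuum revision itself takes the
    retained count as an input and does not recompute it.
    Returns a boolean Series indexed by patient_id.
    """
    from .dates import add_months  # local import to avoid cycle at module load

    if labs.empty:
        return pd.Series(dtype=bool)
    vls = labs.loc[
        labs["kind"].eq("VL")
        & labs["test_date"].ge(pd.Timestamp(window.in_care_start))
        & labs["test_date"].lt(pd.Timestamp(window.in_care_end))
    ]

    def _retained(dates: pd.Series) -> bool:
        ds = sorted(d.date() if isinstance(d, (pd.Timestamp, dt.datetime)) else d
                    for d in dates)
        return bool(ds) and ds[-1] >= add_months(ds[0], 3)

    if vls.empty:
        return pd.Series(dtype=bool)
    return vls.groupby("patient_id")["test_date"].apply(_retained)
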