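"""Synthetic surveillance + clinic extracts with known ground truth.

No patient-level study data are publicly deposited, so every downstream
stage is exercised against a simulated statewide cohort.  The generator
places clinic visits, viral loads, CD4 counts and scheduled appointments so
that each patient

* satisfies the in-care definition (≥1 visit and ≥1 VL in the in-care
  year) — the cohort entering the cycle is, by construction, the in-care
  population of the previous 12 months;
* realises an assigned Box class exactly (presence/absence of visit and VL
  in the OOC window);
* realises an assigned case-conference disposition exactly: only the
  intended stepwise rule fires.  Well patients get two adjacent
  undetectable VLs ≥6 calendar months apart and nothing detectable;
  every non-well patient whose most recent in-care VL is undetectable gets
  an early *detectable* VL so the well-patient rule cannot fire by
  accident; recent-visit patients get a lag-period visit; upcoming-visit
  patients get an appointment within 3 months of the data request; flag
  dispositions set the corresponding status flag and an annotation row.

Default margins are the study cohort's: box mix (0, 763, 1342, 853)/2958,
disposition mix 499 well / 946 recent / 398 upcoming / 624 randomizable
with the residual 491 spread evenly over the seven flag dispositions,
demographic margins from the published totals, last in-care CD4 bins
(270, 211, 593, 1578, 306 missing)/2958 and VL detectability
(2108, 840)/2948, 23 clinics, and a 31/241 missed-appointment probability
for the watchlist.  Event dates are uniform within the sub-window each
constraint permits.  Everything is driven by one integer seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dates import add_months, add_months_series
from .types import (
    AGE_GROUP_LEVELS,
    APPOINTMENT_COLUMNS,
    CD4_BINS,
    Disposition,
    EXPOSURE_LEVELS,
    FLAG_DISPOSITIONS,
    FLAG_FOR_DISPOSITION,
    LAB_COLUMNS,
    PATIENT_COLUMNS,
    RACE_LEVELS,
    SEX_LEVELS,
    STATUS_FLAGS,
    VISIT_COLUMNS,
)
from .window import StudyWindow

__all__ = ["CohortConfig", "SimulatedCohort", "simulate_cohort", "write_cohort"]

_N = 2958  # study cohort size anchoring the default margins


def _norm(counts: dict[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def default_box_probs() -> tuple[float, float, float, float]:
    return (0.0, 763 / _N, 1342 / _N, 853 / _N)


def default_disposition_probs() -> dict[str, float]:
    residual = _N - 499 - 946 - 398 - 624  # flag-driven pool, split evenly
    probs = {
        Disposition.WELL_PATIENT.value: 499 / _N,
        Disposition.RECENT_VISIT.value: 946 / _N,
        Disposition.UPCOMING_VISIT.value: 398 / _N,
    }
    for d in FLAG_DISPOSITIONS:
        probs[d.value] = residual / 7 / _N
    probs[Disposition.RANDOMIZABLE.value] = 624 / _N
    return probs


def default_demo_margins() -> dict[str, dict[str, float]]:
    return {
        "age_group": _norm(dict(zip(AGE_GROUP_LEVELS, [239, 388, 618, 1090, 623]))),
        "sex_at_birth": _norm(dict(zip(SEX_LEVELS, [1913, 1045]))),
        "race_ethnicity": _norm(dict(zip(RACE_LEVELS, [997, 1070, 815, 76]))),
        "exposure_category": _norm(
            dict(zip(EXPOSURE_LEVELS, [871, 837, 904, 78, 62, 206]))
        ),
    }


def default_lab_margins() -> dict[str, dict[str, float]]:
    cd4 = dict(zip(CD4_BINS, [270, 211, 593, 1578]))
    cd4["missing"] = 306
    return {
        "cd4": _norm(cd4),
        "vl": _norm({"undetectable": 2108, "detectable": 840}),
    }


_AGE_RANGES = {
    "under_30": (18.0, 30.0),
    "30-39": (30.0, 40.0),
    "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0),
    "over_60": (60.0, 80.0),
}
_CD4_RANGES = {
    "<200": (10.0, 200.0),
    "200-299": (200.0, 300.0),
    "300-499": (300.0, 500.0),
    ">=500": (500.0, 1400.0),
}


@dataclass
class CohortConfig:
    """Knobs of the simulated world; defaults reproduce the study margins."""

    n_patients: int = _N
    seed: int = 0
    window: StudyWindow = field(
        default_factory=lambda: StudyWindow.from_start(dt.date(2017, 1, 1))
    )
    box_probs: tuple[float, float, float, float] = field(
        default_factory=default_box_probs
    )
    #: either one mapping disposition -> prob (applied within every box),
    #: or a mapping box -> such a mapping.
    disposition_probs: dict = field(default_factory=default_disposition_probs)
    demo_margins: dict = field(default_factory=default_demo_margins)
    lab_margins: dict = field(default_factory=default_lab_margins)
    n_clinics: int = 23
    miss_appointment_prob: float = 31 / 241

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_clinics < 1:
            raise ValueError("n_clinics must be >= 1")
        if not 0.0 <= self.miss_appointment_prob <= 1.0:
            raise ValueError("miss_appointment_prob must be in [0, 1]")
        _check_probs("box_probs", self.box_probs)
        for probs in self._disposition_probs_by_box().values():
            _check_probs("disposition_probs", probs.values())
        for name, margin in {**self.demo_margins, **self.lab_margins}.items():
            _check_probs(name, margin.values())
        w = self.window
        if add_months(w.in_care_start, 7) > w.in_care_end:
            raise ValueError(
                "in-care period too short to place two consecutive well-patient "
                "VLs at least 6 months apart; need an in-care span of >= 7 "
                f"calendar months, got {w.in_care_start}..{w.in_care_end}"
            )
        if add_months(w.in_care_start, 18) > w.ooc_end:
            raise ValueError(
                "study window must span >= 18 months from in_care_start to ooc_end"
            )

    def _disposition_probs_by_box(self) -> dict[str, dict[str, float]]:
        keys = set(self.disposition_probs)
        if keys <= {"B", "C", "D"} and keys:
            return {b: dict(self.disposition_probs[b]) for b in ("B", "C", "D")}
        return {b: dict(self.disposition_probs) for b in ("B", "C", "D")}

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["window"] = self.window.to_dict()
        d["box_probs"] = list(self.box_probs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["window"] = StudyWindow.from_dict(d["window"])
        d["box_probs"] = tuple(d["box_probs"])
        return cls(**d)


def _check_probs(name, values) -> None:
    values = list(values)
    if any(v < 0 for v in values):
        raise ValueError(f"{name}: probabilities must be non-negative")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities must sum to 1, got {sum(values)!r}")


@dataclass
class SimulatedCohort:
    patients: pd.DataFrame
    visits: pd.DataFrame
    labs: pd.DataFrame
    appointments: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CohortConfig
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient_id", "disposition_code", "note"]
        )
    )


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate one reporting cycle's extracts with ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    w = config.window
    ics = pd.Timestamp(w.in_care_start)
    ice = pd.Timestamp(w.in_care_end)
    oce = pd.Timestamp(w.ooc_end)
    drd = pd.Timestamp(w.data_request_date)
    L1 = (ice - ics).days
    L2 = (oce - ice).days
    L3 = (drd - oce).days
    H = (pd.Timestamp(w.upcoming_visit_horizon) - drd).days

    pid = np.array([f"P{i:06d}" for i in range(n)])
    clinic = np.array(
        [f"C{k + 1:02d}" for k in rng.integers(0, config.n_clinics, size=n)]
    )
    box = rng.choice(np.array(["A", "B", "C", "D"]), size=n, p=np.asarray(config.box_probs))

    disp = np.full(n, "", dtype=object)
    by_box = config._disposition_probs_by_box()
    for b, probs in by_box.items():
        mask = box == b
        if mask.any():
            names = np.array(list(probs), dtype=object)
            p = np.asarray(list(probs.values()), dtype=float)
            disp[mask] = rng.choice(names, size=int(mask.sum()), p=p / p.sum())

    # --- demographics -----------------------------------------------------
    demo = {}
    for col, margin in config.demo_margins.items():
        levels = np.array(list(margin), dtype=object)
        p = np.asarray(list(margin.values()), dtype=float)
        demo[col] = rng.choice(levels, size=n, p=p / p.sum())
    lo = np.array([_AGE_RANGES[g][0] for g in demo["age_group"]])
    hi = np.array([_AGE_RANGES[g][1] for g in demo["age_group"]])
    age_years = rng.uniform(lo, hi)
    birth = ics - pd.to_timedelta(np.round(age_years * 365.25), unit="D")

    flags = {f: np.zeros(n, dtype=bool) for f in STATUS_FLAGS}
    ann_rows = []
    for d in FLAG_DISPOSITIONS:
        mask = disp == d.value
        flags[FLAG_FOR_DISPOSITION[d]][mask] = True
        for p_ in pid[mask]:
            ann_rows.append((p_, d.value, "clinic review"))

    visit_rows: list[pd.DataFrame] = []
    lab_rows: list[pd.DataFrame] = []

    def _visits(mask: np.ndarray, origin: pd.Timestamp, span: int) -> None:
        m = int(mask.sum())
        if m:
            days = rng.integers(0, span, size=m)
            visit_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pid[mask],
                        "clinic_id": clinic[mask],
                        "visit_date": origin + pd.to_timedelta(days, unit="D"),
                    }
                )
            )

    def _labs(ids, dates, kind: str, values) -> None:
        if len(ids):
            lab_rows.append(
                pd.DataFrame(
                    {"patient_id": ids, "test_date": dates, "kind": kind,
                     "value": np.asarray(values, dtype=float)}
                )
            )

    # --- in-care year: everyone gets a visit and >=1 VL -------------------
    _visits(np.ones(n, dtype=bool), ics, L1)

    well = disp == Disposition.WELL_PATIENT.value
    nonwell = ~well

    m = int(well.sum())
    if m:
        v1_max = max(L1 - 185, 1)  # leave room for +6 months inside the year
        d1 = ics + pd.to_timedelta(rng.integers(0, min(61, v1_max), size=m), unit="D")
        d1 = pd.Series(d1)
        d2 = add_months_series(d1, 6) + pd.to_timedelta(
            rng.integers(0, 46, size=m), unit="D"
        )
        d2 = d2.clip(upper=ice - pd.Timedelta(days=1))
        _labs(pid[well], d1.to_numpy(), "VL", rng.uniform(0, 20, size=m))
        _labs(pid[well], d2.to_numpy(), "VL", rng.uniform(0, 20, size=m))

    m = int(nonwell.sum())
    if m:
        vl_margin = config.lab_margins["vl"]
        und = rng.random(m) < vl_margin["undetectable"] / (
            vl_margin["undetectable"] + vl_margin["detectable"]
        )
        last_day = rng.integers(L1 // 2, L1, size=m)
        last_date = ics + pd.to_timedelta(last_day, unit="D")
        value = np.where(
            und,
            rng.uniform(0, 20, size=m),
            np.exp(rng.uniform(np.log(21.0), np.log(1e5), size=m)),
        )
        _labs(pid[nonwell], last_date, "VL", value)
        # an early detectable VL prevents an undetectable pair from spanning
        # 6 months and firing the well-patient rule by accident
        if und.any():
            breaker_date = ics + pd.to_timedelta(
                rng.integers(0, 31, size=int(und.sum())), unit="D"
            )
            _labs(
                pid[nonwell][und],
                breaker_date,
                "VL",
                np.exp(rng.uniform(np.log(1e3), np.log(1e5), size=int(und.sum()))),
            )

    # --- last in-care CD4 --------------------------------------------------
    cd4_margin = dict(config.lab_margins["cd4"])
    cd4_levels = np.array(list(cd4_margin), dtype=object)
    cd4_p = np.asarray(list(cd4_margin.values()), dtype=float)
    cd4_bin = rng.choice(cd4_levels, size=n, p=cd4_p / cd4_p.sum())
    has_cd4 = cd4_bin != "missing"
    m = int(has_cd4.sum())
    if m:
        lo = np.array([_CD4_RANGES[b][0] for b in cd4_bin[has_cd4]])
        hi = np.array([_CD4_RANGES[b][1] for b in cd4_bin[has_cd4]])
        _labs(
            pid[has_cd4],
            ics + pd.to_timedelta(rng.integers(0, L1, size=m), unit="D"),
            "CD4",
            np.floor(rng.uniform(lo, hi)),
        )

    # --- OOC window events realise the box ---------------------------------
    _visits(np.isin(box, ["A", "C"]), ice, L2)
    has_ooc_vl = np.isin(box, ["A", "B"])
    m = int(has_ooc_vl.sum())
    if m:
        vl_margin = config.lab_margins["vl"]
        p_und = vl_margin["undetectable"] / (
            vl_margin["undetectable"] + vl_margin["detectable"]
        )
        und = well[has_ooc_vl] | (rng.random(m) < p_und)
        _labs(
            pid[has_ooc_vl],
            ice + pd.to_timedelta(rng.integers(0, L2, size=m), unit="D"),
            "VL",
            np.where(
                und,
                rng.uniform(0, 20, size=m),
                np.exp(rng.uniform(np.log(21.0), np.log(1e5), size=m)),
            ),
        )

    # --- lag-period visit for RECENT_VISIT ---------------------------------
    _visits(disp == Disposition.RECENT_VISIT.value, oce, L3)

    # --- appointments for UPCOMING_VISIT -----------------------------------
    upc = disp == Disposition.UPCOMING_VISIT.value
    m = int(upc.sum())
    appointments = pd.DataFrame(columns=APPOINTMENT_COLUMNS)
    if m:
        kept = np.where(
            rng.random(m) < config.miss_appointment_prob, "missed", "kept"
        )
        appointments = pd.DataFrame(
            {
                "patient_id": pid[upc],
                "clinic_id": clinic[upc],
                "scheduled_date": drd
                + pd.to_timedelta(rng.integers(0, H, size=m), unit="D"),
                "kept": kept,
            }
        )

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_date": birth,
            "sex_at_birth": demo["sex_at_birth"],
            "race_ethnicity": demo["race_ethnicity"],
            "exposure_category": demo["exposure_category"],
            "clinic_id": clinic,
            **flags,
        }
    )[PATIENT_COLUMNS]

    visits = (
        pd.concat(visit_rows, ignore_index=True)
        .sort_values(["patient_id", "visit_date", "clinic_id"])
        .reset_index(drop=True)[VISIT_COLUMNS]
    )
    labs = (
        pd.concat(lab_rows, ignore_index=True)
        .sort_values(["patient_id", "test_date", "kind", "value"])
        .reset_index(drop=True)[LAB_COLUMNS]
    )
    appointments = appointments.sort_values(
        ["patient_id", "scheduled_date"]
    ).reset_index(drop=True)[APPOINTMENT_COLUMNS]

    ground_truth = pd.DataFrame(
        {
            "patient_id": pid,
            "true_box": box,
            # disposition is defined only for the potentially-OOC boxes
            "true_disposition": np.where(box == "A", pd.NA, disp),
            # "still in care during the OOC window" — i.e. Box A; every
            # generated patient meets the 12-month in-care definition
            "true_in_care": box == "A",
        }
    )

    annotations = pd.DataFrame(
        ann_rows, columns=["patient_id", "disposition_code", "note"]
    ).sort_values(["patient_id"]).reset_index(drop=True)

    return SimulatedCohort(
        patients=patients,
        visits=visits,
        labs=labs,
        appointments=appointments,
        ground_truth=ground_truth,
        config=config,
        annotations=annotations,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the extracts as the CSV dialect the pipeline reads.

    Byte-identical for a given config (rows are deterministically sorted,
    dates ISO 8601).  Returns the mapping of logical name -> path.
    """
    from . import io as d2c_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "clinic_visits": out / "clinic_visits.csv",
        "appointments": out / "appointments.csv",
        "surveillance_labs": out / "surveillance_labs.csv",
        "ground_truth": out / "ground_truth.csv",
        "annotations": out / "annotations.csv",
        "config": out / "cohort_config.yaml",
    }
    d2c_io.write_patients(cohort.patients, paths["patients"])
    d2c_io.write_visits(cohort.visits, paths["clinic_visits"])
    d2c_io.write_appointments(cohort.appointments, paths["appointments"])
    d2c_io.write_labs(cohort.labs, paths["surveillance_labs"])
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    cohort.annotations.to_csv(paths["annotations"], index=False)
    cohort.config.to_yaml(paths["config"])
    return paths
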