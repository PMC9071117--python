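"""One full reconciliation cycle, end to end.

Chains the stages exactly as a reporting cycle runs in practice: simulate
(or load) the extracts, read them back through the flat-file layer, join
clinic and surveillance streams, classify boxes, run the case conference,
resolve the watchlist, randomize the final eligible set, account for the
flow, and fold the non-randomizable fraction into a revised care-continuum
estimate.  Used by the CLI's ``all`` subcommand and importable directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as d2c_io
from .conference import resolve_watchlist, run_case_conference
from .continuum import (
    ContinuumInputs,
    nonrandomizable_fraction,
    revise_continuum,
)
from .eligibility import classify_cohort, last_in_care_labs_cohort
from .randomization import randomize
from .reporting import flow_accounting
from .synthetic import CohortConfig, simulate_cohort, write_cohort
from .types import Disposition

__all__ = ["CycleResult", "run_cycle_from_files", "run_simulated_cycle"]


def _continuum_from_cycle(
    conference: pd.DataFrame,
    assignments: pd.DataFrame,
    flow: dict,
    continuum_config: dict | None,
) -> dict | None:
    """Continuum revision fed by the cycle's own non-randomizable fraction."""
    if continuum_config is None:
        return None
    nonrandomized = conference.loc[
        ~conference["patient_id"].isin(assignments["patient_id"])
    ]
    if not len(nonrandomized) or not flow["potentially_ooc"]:
        return None
    shares = (
        nonrandomized["box"].value_counts(normalize=True)
        .reindex(["B", "C", "D"]).fillna(0.0)
    )
    inputs = ContinuumInputs(
        prevalent=int(continuum_config["prevalent"]),
        retained=int(continuum_config["retained"]),
        nonrandomizable_frac=nonrandomizable_fraction(
            len(nonrandomized), flow["potentially_ooc"]
        ),
        box_shares_nonrandomized=tuple(shares),
    )
    return revise_continuum(inputs).to_dict()


@dataclass
class CycleResult:
    boxes: pd.DataFrame
    last_labs: pd.DataFrame
    conference: pd.DataFrame
    watchlist_counts: dict
    assignments: pd.DataFrame
    flow: dict
    continuum: dict | None
    manifest: dict


def run_cycle_from_files(
    in_dir: str | Path,
    window,
    seed: int,
    *,
    out_dir: str | Path | None = None,
    continuum_config: dict | None = None,
) -> CycleResult:
    """Run a cycle on extracts already on disk in *in_dir*.

    Expects clinic_visits.csv, appointments.csv, surveillance_labs.csv and
    patients.csv (annotations.csv optional).  When *out_dir* is given, all
    stage outputs and a manifest are written there.  *continuum_config*
    (keys ``prevalent``, ``retained``) triggers the continuum revision using
    the cycle's own non-randomizable fraction and box composition.
    """
    in_dir = Path(in_dir)
    clinic = d2c_io.read_clinic_extract(
        in_dir / "clinic_visits.csv", in_dir / "appointments.csv"
    )
    labs, _ = d2c_io.read_surveillance_extract(in_dir / "surveillance_labs.csv")
    patients = d2c_io.read_patients(in_dir / "patients.csv")
    ann_path = in_dir / "annotations.csv"
    annotations = pd.read_csv(ann_path, dtype=str) if ann_path.exists() else None

    joined, exceptions = d2c_io.join_surveillance(clinic.visits, labs, patients)
    visits_ok = clinic.visits.loc[clinic.visits["patient_id"].isin(patients["patient_id"])]
    labs_ok = labs.loc[labs["patient_id"].isin(patients["patient_id"])]

    boxes = classify_cohort(patients, visits_ok, labs_ok, window)
    last_labs = last_in_care_labs_cohort(patients, labs_ok, window)
    conference = run_case_conference(
        boxes, patients, visits_ok, labs_ok, clinic.appointments, window,
        annotations=annotations,
    )
    resolution = resolve_watchlist(conference, clinic.appointments)
    eligible_ids = pd.concat(
        [
            conference.loc[
                conference["disposition"].eq(Disposition.RANDOMIZABLE.value),
                ["patient_id"],
            ],
            resolution.additions[["patient_id"]],
        ],
        ignore_index=True,
    )
    eligible = eligible_ids.merge(
        patients[["patient_id", "clinic_id"]], on="patient_id", how="left"
    )
    assignments = randomize(eligible, seed)
    flow = flow_accounting(boxes, conference, resolution.counts, assignments)

    continuum_report = _continuum_from_cycle(
        conference, assignments, flow, continuum_config
    )

    manifest = {
        "seed": seed,
        "window": window.to_dict(),
        "n_patients": int(len(patients)),
        "n_visits": int(len(clinic.visits)),
        "n_labs": int(len(labs)),
        "n_appointments": int(len(clinic.appointments)),
        "n_exceptions": int(len(exceptions)),
        "flow": flow,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        boxes.merge(last_labs, on="patient_id").to_csv(out / "boxes.csv", index=False)
        conference.to_csv(out / "conference_results.csv", index=False)
        conference.loc[conference["watchlist_flag"]].to_csv(
            out / "watchlist.csv", index=False
        )
        assignments.to_csv(out / "assignments.csv", index=False)
        exceptions.to_csv(out / "exceptions.csv", index=False)
        (out / "flow_report.json").write_text(json.dumps(flow, indent=2))
        if continuum_report is not None:
            (out / "continuum_report.json").write_text(
                json.dumps(continuum_report, indent=2)
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return CycleResult(
        boxes=boxes,
        last_labs=last_labs,
        conference=conference,
        watchlist_counts=resolution.counts,
        assignments=assignments,
        flow=flow,
        continuum=continuum_report,
        manifest=manifest,
    )


def run_simulated_cycle(
    config: CohortConfig,
    *,
    out_dir: str | Path | None = None,
    continuum_config: dict | None = None,
    via_files: bool = False,
):
    """Simulate a cohort and run the full cycle on it.

    With ``via_files=True`` (requires *out_dir*) the extracts are written
    and read back through the flat-file layer, exercising the same path a
    production cycle uses.  Returns ``(cohort, CycleResult)``.
    """
    cohort = simulate_cohort(config)
    if via_files:
        if out_dir is None:
            raise ValueError("via_files=True requires out_dir")
        write_cohort(cohort, out_dir)
        result = run_cycle_from_files(
            out_dir, config.window, config.seed,
            out_dir=out_dir, continuum_config=continuum_config,
        )
        return cohort, result
    # in-memory fast path (identical logic, no disk round-trip)
    boxes = classify_cohort(cohort.patients, cohort.visits, cohort.labs, config.window)
    last_labs = last_in_care_labs_cohort(cohort.patients, cohort.labs, config.window)
    conference = run_case_conference(
        boxes, cohort.patients, cohort.visits, cohort.labs,
        cohort.appointments, config.window, annotations=cohort.annotations,
    )
    resolution = resolve_watchlist(conference, cohort.appointments)
    eligible = pd.concat(
        [
            conference.loc[
                conference["disposition"].eq(Disposition.RANDOMIZABLE.value),
                ["patient_id"],
            ],
            resolution.additions[["patient_id"]],
        ],
        ignore_index=True,
    ).merge(cohort.patients[["patient_id", "clinic_id"]], on="patient_id", how="left")
    assignments = randomize(eligible, config.seed)
    flow = flow_accounting(boxes, conference, resolution.counts, assignments)
    continuum_report = _continuum_from_cycle(
        conference, assignments, flow, continuum_config
    )
    result = CycleResult(
        boxes=boxes,
        last_labs=last_labs,
        conference=conference,
        watchlist_counts=resolution.counts,
        assignments=assignments,
        flow=flow,
        continuum=continuum_report,
        manifest={"seed": config.seed, "window": config.window.to_dict(),
                  "n_patients": config.n_patients, "flow": flow},
    )
    return cohort, result
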