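"""1:1 randomization to DIS vs SOC, stratified by clinic.

Within each clinic stratum the eligible patients are shuffled and assigned
in permuted blocks of size 2 (each block contains one DIS and one SOC in
random order), so the per-stratum arm imbalance never exceeds 1 and each
patient's marginal allocation probability is exactly 1/2.  Everything is
driven by a single integer seed, so a run is reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["randomize", "ARMS"]

ARMS = ("DIS", "SOC")


def randomize(eligible: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Assign each eligible patient to DIS or SOC.

    *eligible* needs columns ``patient_id`` and ``clinic_id``; duplicates
    are rejected.  Returns ``patient_id, clinic_id, arm, seed, block_index``
    sorted by (clinic_id, block_index).  An empty input yields an empty
    assignment table, not an error.
    """
    required = {"patient_id", "clinic_id"}
    missing = required - set(eligible.columns)
    if missing:
        raise ValueError(f"eligible table is missing columns: {sorted(missing)}")
    if eligible["patient_id"].duplicated().any():
        dup = eligible.loc[eligible["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"patient appears more than once in eligible set: {dup}")
    if eligible["clinic_id"].isna().any():
        raise ValueError("every eligible patient must have a clinic_id")

    rng = np.random.default_rng(seed)
    rows = []
    # deterministic stratum order, then a seeded shuffle within each stratum
    ordered = eligible.sort_values(["clinic_id", "patient_id"])
    for clinic, grp in ordered.groupby("clinic_id", sort=True):
        ids = grp["patient_id"].to_numpy()
        rng.shuffle(ids)
        for block, start in enumerate(range(0, len(ids), 2)):
            pair = ids[start : start + 2]
            arms = rng.permutation(ARMS)[: len(pair)]
            for pid_, arm in zip(pair, arms):
                rows.append((pid_, clinic, arm, seed, block))
    out = pd.DataFrame(
        rows, columns=["patient_id", "clinic_id", "arm", "seed", "block_index"]
    )
    return out
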