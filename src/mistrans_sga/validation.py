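"""Spot-assay validation of screen hits against the multiplicative model.

Hits from the colony-array screen are validated by remaking each double
mutant, spotting normalized cultures alongside both single mutants and a
control strain, and quantifying spot intensity. Expected double-mutant
growth is the product of the single-mutant fitnesses; a double mutant
growing slower than expected (observed/expected below ``theta``) is a
validated negative interaction.

The rule is a point-estimate comparison, matching typical spot-assay
practice; ``theta`` defaults to 0.9 to give a 10% margin against intensity
noise (a bare "slower than expected" rule has none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationRecord",
    "expected_double",
    "validate_hit",
    "validate_cohort",
]

DEFAULT_THETA = 0.9

#: Roles a spot row can play in a validation table.
ROLES = ("double", "single_ts", "single_trna", "control")


@dataclass
class ValidationRecord:
    strain_id: str
    w_single_ts: float
    w_single_trna: float
    w_double_obs: float
    w_double_expected: float
    ratio_obs_over_exp: float
    validated: bool


def expected_double(w_a: float, w_b: float) -> float:
    """Multiplicative expectation for the double mutant: W_A * W_B."""
    if w_a < 0 or w_b < 0:
        raise ValueError("fitness values must be non-negative")
    return w_a * w_b


def validate_hit(
    strain_id: str,
    double,
    single_ts,
    single_trna,
    control,
    control_trna=None,
    theta: float = DEFAULT_THETA,
) -> ValidationRecord:
    """Score one double mutant from replicate spot intensities.

    Fitness of each strain class is its mean intensity divided by the mean
    control intensity; ``control_trna`` optionally supplies a separate
    control cross for the mistranslating-tRNA single mutant (the
    temperature-sensitive single always uses ``control``). All calls are
    invariant under rescaling every intensity on a plate by a constant.
    """
    c = float(np.mean(np.asarray(control, dtype=float)))
    if c <= 0:
        raise ValueError(f"{strain_id}: control intensity must be positive")
    c2 = c if control_trna is None else float(np.mean(np.asarray(control_trna, float)))
    if c2 <= 0:
        raise ValueError(f"{strain_id}: tRNA control intensity must be positive")
    w_ts = float(np.mean(np.asarray(single_ts, float))) / c
    w_trna = float(np.mean(np.asarray(single_trna, float))) / c2
    w_obs = float(np.mean(np.asarray(double, float))) / c
    w_exp = expected_double(w_ts, w_trna)
    ratio = w_obs / w_exp if w_exp > 0 else np.inf
    return ValidationRecord(
        strain_id=strain_id,
        w_single_ts=w_ts,
        w_single_trna=w_trna,
        w_double_obs=w_obs,
        w_double_expected=w_exp,
        ratio_obs_over_exp=ratio,
        validated=bool(ratio < theta),
    )


def validate_cohort(table: pd.DataFrame, theta: float = DEFAULT_THETA) -> pd.DataFrame:
    """Validate every strain in a long-format spot table.

    Columns: strain, role (double / single_ts / single_trna / control),
    replicate, intensity. Returns one row per strain with fitnesses, the
    expected double fitness, the observed/expected ratio and the call.
    """
    required = {"strain", "role", "intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"spot table needs columns {sorted(required)}")
    bad = set(table["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown spot roles {sorted(bad)}")
    out = []
    for strain, sub in table.groupby("strain", sort=True):
        groups = {role: sub.loc[sub["role"] == role, "intensity"].to_numpy()
                  for role in ROLES}
        for role in ("double", "single_ts", "single_trna", "control"):
            if groups[role].size == 0:
                raise ValueError(f"{strain}: no {role} intensities")
        rec = validate_hit(str(strain), groups["double"], groups["single_ts"],
                           groups["single_trna"], groups["control"],
                           theta=theta)
        out.append(rec)
    return pd.DataFrame({
        "strain": [r.strain_id for r in out],
        "w_single_ts": [r.w_single_ts for r in out],
        "w_single_trna": [r.w_single_trna for r in out],
        "w_double_obs": [r.w_double_obs for r in out],
        "w_double_expected": [r.w_double_expected for r in out],
        "ratio_obs_over_exp": [r.ratio_obs_over_exp for r in out],
        "validated": [r.validated for r in out],
    })
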