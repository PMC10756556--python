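"""Per-stance gait parameters, body-weight normalization and daily aggregation.

Four parameters are computed for every valid stance phase, all normalized by the
animal's body weight (BW) to remove body-size dependence:

``grf_peak_pct``
    Maximum vertical GRF, % of BW.
``grf_mean_pct``
    Stance-average vertical GRF, % of BW.
``t_c_s``
    Contact time, s, from the sample count.
``imp_rel_pct`` / ``imp_abs_pct_s``
    Impulse (time-integral of the stance GRF) normalized by BW and by contact
    time (dimensionless %, decouples gait speed), and by BW only (%BW·s).

Both impulse variants are kept because the t_c-normalized impulse is, by
construction, identical to the stance-average force (integral / t_c == mean),
while the non-normalized variant carries independent contact-time information —
the two behave differently in asymmetry analyses.  Integration uses the
rectangle rule on the uniform grid (sum of samples times the sample period),
which makes the identity exact.

The unit of longitudinal analysis is the daily average: per animal, limb and
measurement day, the mean +/- sample sd over that session's valid phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ForceRecording
from .segmentation import StancePhase

logger = logging.getLogger(__name__)

#: Standard gravity used for %BW <-> N conversion (m/s^2).
G = 9.81

#: Canonical parameter column names, in reporting order.
PARAMETER_NAMES = ("grf_peak_pct", "grf_mean_pct", "t_c_s", "imp_rel_pct", "imp_abs_pct_s")

#: Metadata columns that identify a session in tidy tables.
_META_COLUMNS = ["animal_id", "group", "limb", "day_postop", "session_id"]


@dataclass(frozen=True)
class GaitParameters:
    """Body-weight-normalized parameters of one stance phase."""

    grf_peak_pct: float
    grf_mean_pct: float
    t_c_s: float
    imp_rel_pct: float
    imp_abs_pct_s: float


def compute_parameters(
    phase: StancePhase, body_weight: float, sampling_rate: float | None = None
) -> GaitParameters:
    """Compute the parameter set for one valid stance phase.

    ``body_weight`` is in kg; forces are converted to %BW via BW*g with
    g = 9.81 m/s^2.
    """
    if not phase.valid:
        raise ValidationError("parameters are only defined for valid stance phases")
    if not body_weight > 0:
        raise ValidationError("body_weight must be positive")
    fs = sampling_rate if sampling_rate is not None else phase.sampling_rate
    bw_force = body_weight * G
    f_pct = phase.forces / bw_force * 100.0
    t_c = phase.n_samples / fs
    area = float(f_pct.sum()) / fs  # %BW * s, rectangle rule
    return GaitParameters(
        grf_peak_pct=float(f_pct.max()),
        grf_mean_pct=float(f_pct.mean()),
        t_c_s=t_c,
        imp_rel_pct=area / t_c,
        imp_abs_pct_s=area,
    )


def phase_parameters_table(
    recording: ForceRecording, phases: Iterable[StancePhase]
) -> pd.DataFrame:
    """One row of parameters + session metadata per valid phase of a recording."""
    rows = []
    for idx, phase in enumerate(phases):
        if not phase.valid:
            continue
        p = compute_parameters(phase, recording.body_weight, recording.sampling_rate)
        rows.append(
            {
                "animal_id": recording.animal_id,
                "group": recording.group,
                "limb": recording.limb,
                "day_postop": recording.day_postop,
                "session_id": recording.session_id,
                "phase_idx": idx,
                "grf_peak_pct": p.grf_peak_pct,
                "grf_mean_pct": p.grf_mean_pct,
                "t_c_s": p.t_c_s,
                "imp_rel_pct": p.imp_rel_pct,
                "imp_abs_pct_s": p.imp_abs_pct_s,
            }
        )
    return pd.DataFrame(rows, columns=_META_COLUMNS + ["phase_idx", *PARAMETER_NAMES])


def aggregate_daily(parameters: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-phase parameters to daily summaries.

    Groups by (animal, group, limb, day) and reports, per parameter, the mean,
    the sample standard deviation (n-1 denominator; 0 for singleton groups, with
    a logged caution) and the number of valid phases.  Returns a tidy long
    table: animal_id, group, limb, day_postop, parameter, mean, sd, n_phases.
    Empty input yields an empty table, not an error.
    """
    cols = ["animal_id", "group", "limb", "day_postop", "parameter", "mean", "sd", "n_phases"]
    if parameters.empty:
        return pd.DataFrame(columns=cols)
    keys = ["animal_id", "group", "limb", "day_postop"]
    rows = []
    for key, grp in parameters.groupby(keys, sort=True):
        n = len(grp)
        if n == 1:
            logger.warning(
                "daily summary for %s/%s day %s is based on a single phase (sd set to 0)",
                key[0], key[2], key[3],
            )
        for name in PARAMETER_NAMES:
            vals = grp[name].to_numpy(dtype=float)
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            rows.append(dict(zip(keys, key)) | {
                "parameter": name,
                "mean": float(vals.mean()),
                "sd": sd,
                "n_phases": n,
            })
    return pd.DataFrame(rows, columns=cols)
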