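"""End-to-end convenience layer: recordings -> phases -> parameters -> daily means."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import ForceRecording
from .parameters import aggregate_daily, phase_parameters_table
from .segmentation import SegConfig, segment_recording


@dataclass(frozen=True)
class CohortTables:
    """Tidy result tables of a full pipeline run.

    phases      one row per detected phase (valid or not) with timing and flags
    parameters  one row per valid phase with the BW-normalized parameter set
    daily       long-format daily summaries (the unit of longitudinal analysis)
    """

    phases: pd.DataFrame
    parameters: pd.DataFrame
    daily: pd.DataFrame


def analyze_recordings(
    recordings: Iterable[ForceRecording], seg_config: SegConfig | None = None
) -> CohortTables:
    """Segment every recording, extract parameters and aggregate daily means."""
    seg_config = seg_config or SegConfig()
    phase_rows = []
    param_frames = []
    for rec in recordings:
        phases = segment_recording(rec, seg_config)
        for idx, p in enumerate(phases):
            phase_rows.append(
                {
                    "session_id": rec.session_id,
                    "animal_id": rec.animal_id,
                    "group": rec.group,
                    "limb": rec.limb,
                    "day_postop": rec.day_postop,
                    "phase_idx": idx,
                    "start_s": p.start_time,
                    "end_s": p.end_time,
                    "t_c_s": p.t_c,
                    "peak_N": p.peak_force,
                    "valid": p.valid,
                    "exclusion_reason": p.exclusion_reason,
                }
            )
        param_frames.append(phase_parameters_table(rec, phases))
    phases_df = pd.DataFrame(
        phase_rows,
        columns=[
            "session_id", "animal_id", "group", "limb", "day_postop", "phase_idx",
            "start_s", "end_s", "t_c_s", "peak_N", "valid", "exclusion_reason",
        ],
    )
    params_df = (
        pd.concat(param_frames, ignore_index=True) if param_frames else pd.DataFrame()
    )
    return CohortTables(phases=phases_df, parameters=params_df, daily=aggregate_daily(params_df))
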