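"""Reference study protocols run entirely on synthetic cohorts.

These functions wire the generator and the analysis pipeline together under the
study conditions the package defaults encode (control cohort of 3 animals;
operated cohort of 8 with weekly sessions through day 210) and return the
headline quantities: control grand means, the immediate post-operative hindlimb
impulse asymmetry, and the recovery day/rate of the operated hindlimb's peak
force.  They are what the acceptance script and the end-to-end tests execute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asymmetry import asymmetry_series
from .pipeline import CohortTables, analyze_recordings
from .stats import recovery_rate, recovery_time
from .synthetic import (
    CONTROL_HIND,
    CohortConfig,
    T_RECOVER_FORCE,
    T_START,
    cohort_recordings,
    simulate_cohort,
)

#: Hind and fore limb groupings used for pooled control summaries.
HIND_LIMBS = ("IH", "CH")
FORE_LIMBS = ("IF", "CF")


def control_cohort_config(
    seed: int, n_animals: int = 3, n_sessions: int = 10, phases: int = 8, noise_cv: float = 0.05
) -> CohortConfig:
    """Healthy reference cohort: 3 animals, 10 weekly sessions, 8 phases/limb."""
    days = tuple(range(7, 7 * (n_sessions + 1), 7))
    return CohortConfig(
        n_operated=0,
        n_control=n_animals,
        session_days=days,
        phases_per_session=(phases, phases),
        noise_cv=noise_cv,
        rng_seed=seed,
    )


def run_control_study(seed: int) -> dict:
    """Full pipeline on the control cohort; grand means over valid phases.

    Returns hindlimb peak/mean/contact-time/relative-impulse and forelimb
    relative-impulse grand means, with the phase counts they are based on.
    """
    sims = simulate_cohort(control_cohort_config(seed))
    tables = analyze_recordings(cohort_recordings(sims))
    params = tables.parameters
    hind = params[params["limb"].isin(HIND_LIMBS)]
    fore = params[params["limb"].isin(FORE_LIMBS)]
    return {
        "hind_grf_peak_pct": float(hind["grf_peak_pct"].mean()),
        "hind_grf_mean_pct": float(hind["grf_mean_pct"].mean()),
        "hind_t_c_s": float(hind["t_c_s"].mean()),
        "hind_imp_rel_pct": float(hind["imp_rel_pct"].mean()),
        "fore_imp_rel_pct": float(fore["imp_rel_pct"].mean()),
        "n_hind_phases": int(len(hind)),
        "n_fore_phases": int(len(fore)),
    }


def operated_cohort_config(
    seed: int,
    session_days: tuple[int, ...] | None = None,
    n_animals: int = 8,
) -> CohortConfig:
    """Operated cohort at package defaults (weekly sessions through day 210)."""
    kwargs = {} if session_days is None else {"session_days": session_days}
    return CohortConfig(n_operated=n_animals, n_control=0, rng_seed=seed, **kwargs)


def run_day7_asymmetry_study(seed: int) -> dict:
    """Immediate post-operative (day 7) asymmetries of the operated cohort.

    Per animal, daily-mean limb parameters feed the asymmetry index; the cohort
    mean over the 8 operated animals is reported for the non-t_c-normalized
    impulse (the variant that reacts to both the force deficit and the
    shortened contact) and for the two GRF parameters.
    """
    config = operated_cohort_config(seed, session_days=(7,))
    sims = simulate_cohort(config)
    tables = analyze_recordings(cohort_recordings(sims))

    def hind_mean(parameter: str) -> float:
        series = asymmetry_series(tables.daily, parameter)
        return float(series[series["pair"] == "hind"]["asymmetry_pct"].mean())

    return {
        "hind_imp_abs_asym_pct": hind_mean("imp_abs_pct_s"),
        "hind_grf_peak_asym_pct": hind_mean("grf_peak_pct"),
        "hind_grf_mean_asym_pct": hind_mean("grf_mean_pct"),
        "n_animals": config.n_operated,
    }


def run_recovery_study(seed: int) -> dict:
    """Recovery day and linear recovery rate of the operated hindlimb peak GRF.

    The operated cohort's per-animal daily means of IH grf_peak_pct are pooled
    into a grand daily-mean trajectory; recovery time is its first persistent
    entry into the +/-5% band around the hindlimb control peak, and the
    recovery rate is the OLS slope over the consolidation window (days 7-160)
    in %BW per month.
    """
    config = operated_cohort_config(seed)
    sims = simulate_cohort(config)
    tables = analyze_recordings(cohort_recordings(sims))
    daily = tables.daily
    ih_peak = daily[(daily["limb"] == "IH") & (daily["parameter"] == "grf_peak_pct")]
    grand = ih_peak.groupby("day_postop")["mean"].mean().sort_index()
    days = grand.index.to_numpy(dtype=float)
    values = grand.to_numpy(dtype=float)
    t_rec = recovery_time(days, values, CONTROL_HIND["peak_pct"], tolerance_frac=0.05)
    rate = recovery_rate(days, values, window=(T_START, T_RECOVER_FORCE))
    return {
        "recovery_day": t_rec,
        "recovery_rate_pct_bw_per_month": float(rate),
        "n_sessions": int(days.size),
        "n_animals": config.n_operated,
    }
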