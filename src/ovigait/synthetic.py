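"""Synthetic vertical-GRF data with the statistical structure of an ovine
bone-regeneration gait study.

The generator produces force-platform recordings for a longitudinal cohort of
sheep: healthy animals show the characteristic double-peaked ("M-shaped")
hindlimb stance curve, an operated hindlimb shows a sharp single-hump lame
curve that linearly renormalizes over the consolidation period, and the three
non-operated limbs show transient compensatory elevation.  All levels are in
percent of body weight (%BW); forces are converted to newtons via BW*g.

Waveform family
---------------
A stance curve on the unit phase ``s = t/t_c in [0, 1]`` is::

    shape(s) = sin(pi*s)**q * (1 - d * sin(pi*s)**2) * (1 + (a-1)*s)

* ``d`` (dip_depth, 0 <= d < 1) carves the mid-stance valley.  For d above
  q/(q+2) the mid-stance maximum splits into two humps (the M-shape); below it
  the curve is single-humped.
* ``q`` (hump_power, > 0) controls hump sharpness: q = 1 is the plain sine
  product, q > 1 gives the peaked single-maximum curve of an acutely lame limb
  ("punctual" ground contact), q < 1 flattens the top.
* ``a`` (hump_asymmetry) tilts the second hump relative to the first.

The curve is rescaled so its maximum sample equals the requested peak exactly.
Samples are taken at midpoint phase offsets ``s_k = (k + 1/2)/m`` with
``m = round(t_c * fs)``: foot strike and lift-off fall between samples, the
segmented contact time is exactly ``m/fs``, and the sample mean equals the
rectangle-rule stance average used downstream — so a noise-free pipeline run
reproduces the generator's parameter values to calibration precision.

The mean-to-peak ratio of the family is *not* monotone in ``d``: it rises from
2/pi at d = 0 to a maximum at the hump-split point, then falls.  Calibration
therefore works on an explicit branch ("shallow" = smallest d, "deep" = the
M-shaped descending branch).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ResolutionError, ValidationError
from .io import LIMBS, ForceRecording, ManifestEntry, write_force_recording, write_manifest
from .parameters import G

logger = logging.getLogger(__name__)

#: Minimum samples a template may span.
_MIN_SAMPLES = 8


# ---------------------------------------------------------------------------
# Template family


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of one stance-curve template.

    peak_pct   target peak force, %BW (the maximum sample equals it exactly)
    t_c        contact time, s
    dip_depth  mid-stance valley depth d in [0, 1); 0 = no valley
    hump_power sharpness exponent q > 0; 1 = plain sine product
    hump_asymmetry  relative height ramp of the second hump, in (0, 2)
    """

    peak_pct: float
    t_c: float
    dip_depth: float = 0.0
    hump_power: float = 1.0
    hump_asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if not self.peak_pct > 0:
            raise ValidationError("peak_pct must be positive")
        if not self.t_c > 0:
            raise ValidationError("t_c must be positive")
        if not 0.0 <= self.dip_depth < 1.0:
            raise ValidationError("dip_depth must be in [0, 1)")
        if not self.hump_power > 0:
            raise ValidationError("hump_power must be positive")
        if not 0.0 < self.hump_asymmetry < 2.0:
            raise ValidationError("hump_asymmetry must be in (0, 2)")


def _shape(s: np.ndarray, d: float, q: float, a: float) -> np.ndarray:
    sin = np.sin(np.pi * s)
    return sin**q * (1.0 - d * sin**2) * (1.0 + (a - 1.0) * s)


def stance_template(params: TemplateParams, sampling_rate: float) -> np.ndarray:
    """Sampled stance curve in %BW for one foot contact.

    Returns ``m = round(t_c * fs)`` strictly positive samples at midpoint phase
    offsets; the maximum equals ``peak_pct`` to machine precision and the
    implied contact boundaries lie within half a sample of the first/last
    sample.
    """
    m = round(params.t_c * sampling_rate)
    if m < _MIN_SAMPLES:
        raise ResolutionError(
            f"contact time {params.t_c:.3f}s spans only {m} samples at "
            f"{sampling_rate:g} Hz (need >= {_MIN_SAMPLES})"
        )
    s = (np.arange(m) + 0.5) / m
    y = _shape(s, params.dip_depth, params.hump_power, params.hump_asymmetry)
    return params.peak_pct * y / y.max()


def template_mean_to_peak(
    dip_depth: float = 0.0,
    hump_power: float = 1.0,
    hump_asymmetry: float = 1.0,
    n_samples: int = 2048,
) -> float:
    """Numeric mean/peak ratio of the template family at given shape parameters."""
    s = (np.arange(n_samples) + 0.5) / n_samples
    y = _shape(s, dip_depth, hump_power, hump_asymmetry)
    return float(y.mean() / y.max())


def split_depth(hump_power: float) -> float:
    """Dip depth above which the single mid-stance maximum splits into two humps."""
    return hump_power / (hump_power + 2.0)


def solve_dip_depth(
    target_mean_to_peak: float,
    hump_power: float = 1.0,
    hump_asymmetry: float = 1.0,
    n_samples: int = 2048,
    branch: str = "shallow",
    tol: float = 1e-6,
) -> float:
    """Invert the mean/peak ratio for the valley depth ``d``.

    The ratio rises from the half-sine value at d = 0 to an interior maximum
    (near d = 0.5 for q = 1), then falls towards the deep-valley limit, so most
    targets have two preimages.  ``branch="shallow"`` returns the smallest d;
    ``branch="deep"`` returns the d on the descending branch, where the curve
    is reliably M-shaped.  Targets outside the achievable interval raise
    :class:`CalibrationError` reporting that interval.
    """
    if branch not in ("shallow", "deep"):
        raise ValidationError("branch must be 'shallow' or 'deep'")
    q, a = hump_power, hump_asymmetry

    def ratio(d: float) -> float:
        return template_mean_to_peak(d, q, a, n_samples)

    d_hi = 1.0 - 1e-9
    # locate the interior ratio maximum on a grid to split the two branches
    grid = np.linspace(0.0, d_hi, 257)
    r_grid = np.array([ratio(d) for d in grid])
    d_at_max = float(grid[int(np.argmax(r_grid))])
    r0, r_max, r_deep = ratio(0.0), float(r_grid.max()), ratio(d_hi)
    r_min = min(r0, r_deep)
    t = target_mean_to_peak
    if not (r_min - tol <= t <= r_max + tol):
        raise CalibrationError(
            f"mean/peak ratio {t:.4f} outside the achievable interval "
            f"[{r_min:.4f}, {r_max:.4f}] for hump_power={q:g}"
        )
    if branch == "shallow" and t >= r0 - tol:
        if abs(t - r0) <= tol:
            return 0.0
        t_clip = min(t, r_max)
        return float(brentq(lambda d: ratio(d) - t_clip, 0.0, d_at_max, xtol=1e-10))
    # descending branch (also the only branch for targets below the d=0 ratio)
    t_clip = min(max(t, r_deep), r_max)
    return float(brentq(lambda d: ratio(d) - t_clip, d_at_max, d_hi, xtol=1e-10))


def calibrate_template(
    peak_pct: float,
    mean_pct: float,
    t_c: float,
    sampling_rate: float,
    style: str = "m_shape",
    hump_asymmetry: float = 1.0,
) -> TemplateParams:
    """Solve the shape so the *sampled* template hits both peak and stance mean.

    The ratio is inverted on the discrete midpoint grid actually used at
    ``sampling_rate`` so that a noise-free pipeline run reproduces ``mean_pct``.

    ``style="m_shape"`` fixes q = 1 and solves the valley depth on the
    descending (double-humped) branch — the healthy-limb morphology.
    ``style="single_hump"`` fixes d = 0 and solves the sharpness exponent q —
    the lame-limb morphology (q > 1 for a peaked curve carrying little load,
    q < 1 for a flattened one).
    """
    if not 0 < mean_pct <= peak_pct:
        raise ValidationError("need 0 < mean_pct <= peak_pct")
    m = round(t_c * sampling_rate)
    if m < _MIN_SAMPLES:
        raise ResolutionError(f"t_c {t_c:.3f}s too short at {sampling_rate:g} Hz")
    r = mean_pct / peak_pct
    if style == "m_shape":
        d = solve_dip_depth(r, 1.0, hump_asymmetry, n_samples=m, branch="deep")
        return TemplateParams(peak_pct, t_c, dip_depth=d, hump_asymmetry=hump_asymmetry)
    if style == "single_hump":
        q_lo, q_hi = 0.25, 4.0

        def ratio(q: float) -> float:
            return template_mean_to_peak(0.0, q, hump_asymmetry, n_samples=m)

        r_hi, r_lo = ratio(q_lo), ratio(q_hi)  # ratio decreases with q
        if not r_lo <= r <= r_hi:
            raise CalibrationError(
                f"single-hump mean/peak {r:.4f} outside achievable [{r_lo:.4f}, {r_hi:.4f}]"
            )
        q = float(brentq(lambda v: ratio(v) - r, q_lo, q_hi, xtol=1e-10))
        return TemplateParams(
            peak_pct, t_c, dip_depth=0.0, hump_power=q, hump_asymmetry=hump_asymmetry
        )
    raise ValidationError("style must be 'm_shape' or 'single_hump'")


# ---------------------------------------------------------------------------
# Longitudinal trajectories


@dataclass(frozen=True)
class TrajectoryParams:
    """Piecewise-linear recovery of one parameter: post-operative value at the
    first walking day, linear to the control value at the recovery day, constant
    after.  ``residual_frac`` keeps a persistent fractional deviation (towards
    the post-operative side) beyond recovery."""

    v_postop: float
    v_control: float
    t_start: float = 7.0
    t_recovery: float = 160.0
    residual_frac: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_recovery > self.t_start:
            raise ValidationError("t_recovery must exceed t_start")
        if not self.v_control > 0:
            raise ValidationError("v_control must be positive")


def trajectory_value(params: TrajectoryParams, day: float) -> float:
    """Expected parameter value on a given post-operative day."""
    if day < 0:
        raise ValidationError("day must be >= 0")
    if day < params.t_start:
        raise ValidationError(
            f"day {day:g} precedes first walking day {params.t_start:g} (animal not yet walking)"
        )
    sign = 1.0 if params.v_postop >= params.v_control else -1.0
    v_end = params.v_control * (1.0 + sign * params.residual_frac)
    if day >= params.t_recovery:
        return v_end
    frac = (day - params.t_start) / (params.t_recovery - params.t_start)
    return params.v_postop + frac * (v_end - params.v_postop)


@dataclass(frozen=True)
class LimbModel:
    """Trajectories of one limb's peak (%BW), stance mean (%BW) and contact
    time (s), plus the day until which the limb keeps the lame single-hump
    morphology (None for limbs that never lose the healthy shape)."""

    peak: TrajectoryParams
    mean: TrajectoryParams
    t_c: TrajectoryParams
    lame_until: float | None = None


#: Healthy (control) stance-curve levels, %BW and s.
CONTROL_HIND = {"peak_pct": 42.0, "mean_pct": 28.0, "t_c": 0.58}
CONTROL_FORE = {"peak_pct": 62.0, "mean_pct": 45.0, "t_c": 0.52}

#: First day the animals walk after surgery (latency/recovery period).
T_START = 7.0
#: Day by which force parameters renormalize to control.
T_RECOVER_FORCE = 160.0
#: Day by which contact times renormalize to control.
T_RECOVER_TC = 200.0


def _const(v: float) -> TrajectoryParams:
    return TrajectoryParams(v, v, t_start=0.0, t_recovery=1.0)


def control_limb_models() -> dict[str, LimbModel]:
    """Constant healthy trajectories for all four limbs."""
    hind = LimbModel(
        peak=_const(CONTROL_HIND["peak_pct"]),
        mean=_const(CONTROL_HIND["mean_pct"]),
        t_c=_const(CONTROL_HIND["t_c"]),
    )
    fore = LimbModel(
        peak=_const(CONTROL_FORE["peak_pct"]),
        mean=_const(CONTROL_FORE["mean_pct"]),
        t_c=_const(CONTROL_FORE["t_c"]),
    )
    return {"IH": hind, "CH": hind, "IF": fore, "CF": fore}


def default_limb_models(severity: float = 1.0) -> dict[str, LimbModel]:
    """Post-operative trajectory defaults for an operated animal.

    The operated hindlimb (IH) starts at peak 23 / stance-mean 11.5 %BW with a
    sharp single-hump curve and a 0.28 s contact, recovering linearly to the
    hindlimb control values (forces by day 160, contact time by day 200).  The
    three non-operated limbs start elevated — contralateral hind stance mean
    38 %BW, forelimbs +11.2 (IF) and +21.7 (CF) %BW above their control mean —
    with their healthy shape (mean/peak ratio) preserved and contact times
    lengthened by 0.05 s, likewise decaying to control.  ``severity`` scales the
    operated limb's post-operative force deficit (1 = the cohort-average
    trajectory; < 1 = more severe lameness).
    """
    ch_mean0 = 38.0
    hind_ratio = CONTROL_HIND["peak_pct"] / CONTROL_HIND["mean_pct"]
    fore_ratio = CONTROL_FORE["peak_pct"] / CONTROL_FORE["mean_pct"]
    if_mean0 = CONTROL_FORE["mean_pct"] + 11.2
    cf_mean0 = CONTROL_FORE["mean_pct"] + 21.7
    return {
        "IH": LimbModel(
            peak=TrajectoryParams(23.0 * severity, CONTROL_HIND["peak_pct"], T_START, T_RECOVER_FORCE),
            mean=TrajectoryParams(11.5 * severity, CONTROL_HIND["mean_pct"], T_START, T_RECOVER_FORCE),
            t_c=TrajectoryParams(0.28, CONTROL_HIND["t_c"], T_START, T_RECOVER_TC),
            lame_until=T_RECOVER_FORCE,
        ),
        "CH": LimbModel(
            peak=TrajectoryParams(ch_mean0 * hind_ratio, CONTROL_HIND["peak_pct"], T_START, T_RECOVER_FORCE),
            mean=TrajectoryParams(ch_mean0, CONTROL_HIND["mean_pct"], T_START, T_RECOVER_FORCE),
            t_c=TrajectoryParams(CONTROL_HIND["t_c"] + 0.05, CONTROL_HIND["t_c"], T_START, T_RECOVER_TC),
        ),
        "IF": LimbModel(
            peak=TrajectoryParams(if_mean0 * fore_ratio, CONTROL_FORE["peak_pct"], T_START, T_RECOVER_FORCE),
            mean=TrajectoryParams(if_mean0, CONTROL_FORE["mean_pct"], T_START, T_RECOVER_FORCE),
            t_c=TrajectoryParams(CONTROL_FORE["t_c"] + 0.05, CONTROL_FORE["t_c"], T_START, T_RECOVER_TC),
        ),
        "CF": LimbModel(
            peak=TrajectoryParams(cf_mean0 * fore_ratio, CONTROL_FORE["peak_pct"], T_START, T_RECOVER_FORCE),
            mean=TrajectoryParams(cf_mean0, CONTROL_FORE["mean_pct"], T_START, T_RECOVER_FORCE),
            t_c=TrajectoryParams(CONTROL_FORE["t_c"] + 0.05, CONTROL_FORE["t_c"], T_START, T_RECOVER_TC),
        ),
    }


def limb_template(model: LimbModel, day: float, sampling_rate: float) -> TemplateParams:
    """Calibrated stance template for one limb on one measurement day."""
    peak = trajectory_value(model.peak, day)
    mean = trajectory_value(model.mean, day)
    t_c = trajectory_value(model.t_c, day)
    lame = model.lame_until is not None and day < model.lame_until
    style = "single_hump" if lame else "m_shape"
    return calibrate_template(peak, mean, t_c, sampling_rate, style=style)


# ---------------------------------------------------------------------------
# Session and cohort simulation


@dataclass(frozen=True)
class PhaseTruth:
    """Ground-truth location and parameters of one generated stance phase."""

    start_index: int
    end_index: int
    peak_pct: float
    t_c: float


@dataclass(frozen=True)
class SimulatedRecording:
    """A generated recording together with its generating ground truth."""

    recording: ForceRecording
    phases: tuple[PhaseTruth, ...]


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def simulate_session(
    templates: Mapping[str, TemplateParams],
    n_phases: "int | Mapping[str, int]",
    noise_cv: float,
    body_weight: float,
    rng: np.random.Generator,
    sampling_rate: float = 50.0,
    gap_s: tuple[float, float] = (0.3, 0.6),
    animal_id: str = "A0",
    day_postop: int = 0,
    session_id: str = "S0",
    group: str = "operated",
) -> dict[str, SimulatedRecording]:
    """Generate one measurement session: one recording per limb.

    Each recording concatenates ``n_phases`` stance templates separated by
    zero-force gaps drawn uniformly from ``gap_s`` seconds.  Per phase, the
    template's peak and contact time are multiplied by independent unit-mean
    lognormal factors with coefficient of variation ``noise_cv`` (step-to-step
    variability); %BW is converted to newtons via BW*g.  Deterministic for a
    fixed generator state.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    out: dict[str, SimulatedRecording] = {}
    for limb in [l for l in LIMBS if l in templates]:
        tp = templates[limb]
        k = n_phases if isinstance(n_phases, int) else int(n_phases[limb])
        if k < 1:
            raise ValidationError("n_phases must be >= 1")
        peak_f = _lognormal_factors(rng, noise_cv, k)
        tc_f = _lognormal_factors(rng, noise_cv, k)
        gaps = rng.uniform(gap_s[0], gap_s[1], size=k + 1)
        chunks: list[np.ndarray] = []
        truth: list[PhaseTruth] = []
        cursor = 0
        for i in range(k):
            gap = np.zeros(round(gaps[i] * sampling_rate))
            chunks.append(gap)
            cursor += gap.size
            noisy = replace(tp, peak_pct=tp.peak_pct * peak_f[i], t_c=tp.t_c * tc_f[i])
            y = stance_template(noisy, sampling_rate)
            chunks.append(y)
            truth.append(
                PhaseTruth(
                    start_index=cursor,
                    end_index=cursor + y.size,
                    peak_pct=noisy.peak_pct,
                    t_c=y.size / sampling_rate,
                )
            )
            cursor += y.size
        chunks.append(np.zeros(round(gaps[k] * sampling_rate)))
        forces_n = np.concatenate(chunks) * body_weight * G / 100.0
        rec = ForceRecording(
            forces=forces_n,
            sampling_rate=sampling_rate,
            animal_id=animal_id,
            limb=limb,
            day_postop=day_postop,
            body_weight=body_weight,
            session_id=session_id,
            group=group,
        )
        out[limb] = SimulatedRecording(recording=rec, phases=tuple(truth))
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Study design of a simulated cohort.

    Defaults emulate the reference study design: 8 operated + 3 control
    animals, weekly sessions from post-operative day 7 through day 210, 7-10
    stance phases per limb and session, 5% step-to-step noise, body weights
    ~ Normal(57.90, 9.62^2) kg truncated at 30 kg, and a mild (3% CV)
    between-animal lognormal factor on the operated limb's post-operative
    force deficit.
    """

    n_operated: int = 8
    n_control: int = 3
    body_weight_mean: float = 57.90
    body_weight_sd: float = 9.62
    body_weight_min: float = 30.0
    session_days: tuple[int, ...] = tuple(range(7, 211, 7))
    phases_per_session: tuple[int, int] = (7, 10)
    noise_cv: float = 0.05
    severity_cv: float = 0.03
    gap_s: tuple[float, float] = (0.3, 0.6)
    sampling_rate: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_operated < 0 or self.n_control < 0 or self.n_operated + self.n_control < 1:
            raise ValidationError("cohort needs at least one animal")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if list(self.session_days) != sorted(self.session_days):
            raise ValidationError("session_days must be sorted ascending")
        lo, hi = self.phases_per_session
        if not 1 <= lo <= hi:
            raise ValidationError("phases_per_session must be an ordered range >= 1")


def _draw_body_weight(rng: np.random.Generator, config: CohortConfig) -> float:
    while True:
        bw = rng.normal(config.body_weight_mean, config.body_weight_sd)
        if bw >= config.body_weight_min:
            return float(bw)


def simulate_cohort(config: CohortConfig) -> list[SimulatedRecording]:
    """Generate the full longitudinal cohort; a pure function of the config.

    Operated animals follow :func:`default_limb_models` (with a per-animal
    severity factor); control animals use the constant healthy templates on the
    same session days.  Session days before the first walking day are skipped
    with a logged warning.
    """
    rng = np.random.default_rng(config.rng_seed)
    sims: list[SimulatedRecording] = []
    animals = [(f"S{i + 1:02d}", "operated") for i in range(config.n_operated)]
    animals += [(f"C{i + 1:02d}", "control") for i in range(config.n_control)]
    lo, hi = config.phases_per_session
    for animal_id, group in animals:
        bw = _draw_body_weight(rng, config)
        if group == "operated":
            severity = float(_lognormal_factors(rng, config.severity_cv, 1)[0])
            models = default_limb_models(severity=severity)
        else:
            models = control_limb_models()
        t_start = max(m.peak.t_start for m in models.values())
        for day in config.session_days:
            if day < t_start:
                logger.warning(
                    "skipping day %s for %s: before first walking day %g", day, animal_id, t_start
                )
                continue
            templates = {
                limb: limb_template(models[limb], day, config.sampling_rate) for limb in LIMBS
            }
            n_phases = {limb: int(rng.integers(lo, hi + 1)) for limb in LIMBS}
            session = simulate_session(
                templates,
                n_phases,
                config.noise_cv,
                bw,
                rng,
                sampling_rate=config.sampling_rate,
                gap_s=config.gap_s,
                animal_id=animal_id,
                day_postop=day,
                session_id=f"{animal_id}-d{day:03d}",
                group=group,
            )
            sims.extend(session[limb] for limb in LIMBS)
    return sims


def cohort_recordings(sims: Sequence[SimulatedRecording]) -> list[ForceRecording]:
    return [s.recording for s in sims]


def write_cohort(sims: Sequence[SimulatedRecording], out_dir: str | Path) -> Path:
    """Write per-recording CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sim in sims:
        rec = sim.recording
        fname = f"{rec.session_id}-{rec.limb}.csv"
        write_force_recording(rec, out_dir / fname)
        entries.append(
            ManifestEntry(
                file=fname,
                animal_id=rec.animal_id,
                limb=rec.limb,
                day_postop=rec.day_postop,
                body_weight=rec.body_weight,
                session_id=rec.session_id,
                group=rec.group,
            )
        )
    manifest_path = out_dir / "manifest.csv"
    write_manifest(entries, manifest_path)
    return manifest_path
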