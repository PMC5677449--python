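"""Synthetic cohorts of spiral-drawing sessions with the study's design.

The real measurements (19 patients, 22 healthy controls drawing spirals
on a 480x800 px smartphone around a single levodopa dose) are not
publicly available, so every downstream stage is exercised on simulated
cohorts that reproduce the measurement design exactly:

* patients tested at -20 (baseline), 0 (dose), 15, 30, 45, 60, 80, 100,
  120, 150, 180, 210, 240, 300 and 360 min from dose;
* healthy controls at 0, 20, 40, 60, 80, 110, 140 and 170 min from
  their first test;
* three ~10 s trials per occasion, event-based irregular sampling;
* six mean UPDRS-III item ratings plus a dyskinesia rating (0-4,
  averaged over three simulated raters) for patients only.

The generative model is deliberately minimal.  Each subject carries a
latent motor-impairment *severity* (healthy ~0.3, early ~1, intermediate
~2, advanced ~3 on an arbitrary scale).  A levodopa dose subtracts a
unimodal effect curve from patient severity (onset delay, peak around
60-100 min, wearing off towards 300-360 min).  Severity feeds the
drawing through two couplings:

* ``irregularity_gain`` scales the amplitude of band-limited
  high-frequency multiplicative noise on the instantaneous drawing
  speed — this is what ApEn picks up;
* ``completion_time_gain`` slows the whole trial down — this acts on
  the score through the 1/completion-time normalization, pushing TIS
  *down* with severity.

The two knobs expose both directions of the severity-to-score coupling;
the defaults put them in balance so that both mechanisms are visible.
Clinical ratings are a clipped monotone map of slow severity plus
per-rater noise; dyskinesia instead tracks the (lagged) medication
effect, peaking at On-with-dyskinesia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import DeviceSpec, RATING_SCALES, SpiralTrial, SubjectRecord, TestOccasion

__all__ = [
    "PATIENT_SCHEDULE",
    "HEALTHY_SCHEDULE",
    "DROPOUT_COUNTS",
    "LevodopaResponse",
    "SimulationConfig",
    "weak_correlation_config",
    "simulate_cohort",
    "severity_time_course",
    "render_trial",
    "ratings_from_severity",
    "simulate_trial_triples",
    "simulate_score_table",
]

#: Patient test schedule: minutes from dose (baseline 20 min before).
PATIENT_SCHEDULE: tuple[float, ...] = (
    -20, 0, 15, 30, 45, 60, 80, 100, 120, 150, 180, 210, 240, 300, 360,
)
#: Healthy-control schedule: minutes from their first test.
HEALTHY_SCHEDULE: tuple[float, ...] = (0, 20, 40, 60, 80, 110, 140, 170)

#: Patients still observed at each post-dose timepoint (0..300 min) in the
#: study, plus a single patient at 360 min; used by the dropout option.
DROPOUT_COUNTS: dict[float, int] = {
    0: 19, 15: 19, 30: 19, 45: 19, 60: 18, 80: 18, 100: 18, 120: 18,
    150: 18, 180: 17, 210: 15, 240: 13, 300: 9, 360: 1,
}


@dataclass(frozen=True)
class LevodopaResponse:
    """Single-dose levodopa effect curve parameters (minutes / latent units).

    The effect is a gamma-shaped unimodal pulse: zero until
    ``onset_delay_min``, rising to ``peak_effect`` at ``peak_time_min``,
    then decaying (wearing off) with rate controlled by ``shape`` —
    larger shape gives a sharper pulse.
    """

    onset_delay_min: float = 10.0
    peak_time_min: float = 70.0
    peak_effect: float = 1.2
    shape: float = 1.0

    def effect(self, minutes: np.ndarray | float) -> np.ndarray:
        """Medication effect (latent severity units removed) at time t."""
        t = np.asarray(minutes, dtype=float)
        tau = (t - self.onset_delay_min) / (self.peak_time_min - self.onset_delay_min)
        tau = np.maximum(tau, 0.0)
        pulse = (tau * np.exp(1.0 - tau)) ** self.shape
        return self.peak_effect * pulse


@dataclass
class SimulationConfig:
    """All knobs of the cohort simulator.

    Counts, schedules, device geometry, trial duration, age and gender
    distributions mirror the study design; the coupling gains and noise
    levels are the generative model's free parameters.
    """

    # cohort composition
    n_healthy: int = 22
    n_early: int = 7
    n_intermediate: int = 8
    n_advanced: int = 4
    seed: int = 0

    # device and task
    device: DeviceSpec = field(default_factory=DeviceSpec)
    trial_duration_s: float = 10.0
    spiral_turns: float = 3.0
    margin_px: float = 30.0

    # event-based sampling: mean inter-event interval and jitter (ms)
    sample_interval_ms: float = 20.0
    sample_jitter_ms: float = 4.0

    # latent severity per group (mean) and between-subject SD
    severity_scale: dict[str, float] = field(
        default_factory=lambda: {
            "healthy": 0.3, "early": 1.0, "intermediate": 2.0, "advanced": 3.0,
        }
    )
    severity_sd: float = 0.25
    occasion_severity_sd: float = 0.1

    # severity -> drawing couplings
    irregularity_gain: float = 0.01  # noise amplitude per severity unit
    occasion_irregularity_sd: float = 0.0  # severity-independent amp noise
    completion_time_gain: float = 0.05  # fractional slowdown per severity unit
    trial_duration_jitter: float = 0.03  # trial-to-trial fractional duration noise
    drift_amplitude: float = 0.15  # low-frequency speed drift (fraction)
    drift_cycles: float = 1.5

    # medication response and ratings
    pd_response: LevodopaResponse = field(default_factory=LevodopaResponse)
    rater_noise_sd: float = 0.3
    rating_slope: float = 1.1  # UPDRS units per severity unit
    rating_floor: float = 0.2  # severity below which UPDRS items rate 0
    dys_gain: float = 0.5  # dyskinesia units per (effect x baseline severity)
    dys_lag_min: float = 10.0

    # demography
    age_mean_patient: float = 71.4
    age_sd_patient: float = 6.3
    age_mean_healthy: float = 64.2
    age_sd_healthy: float = 7.4
    male_fraction_patient: float = 14 / 19
    male_fraction_healthy: float = 16 / 22

    dropout: bool = False

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_early", "n_intermediate", "n_advanced"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.severity_scale.values()):
            raise ValueError("severities must be >= 0")

    @property
    def n_patients(self) -> int:
        return self.n_early + self.n_intermediate + self.n_advanced

    def to_yaml(self, path: str) -> str:
        data = asdict(self)
        data["device"] = asdict(self.device)
        data["pd_response"] = asdict(self.pd_response)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "device" in data and isinstance(data["device"], dict):
            data["device"] = DeviceSpec(**data["device"])
        if "pd_response" in data and isinstance(data["pd_response"], dict):
            data["pd_response"] = LevodopaResponse(**data["pd_response"])
        return cls(**data)


def weak_correlation_config(seed: int = 0) -> SimulationConfig:
    """A regime where TIS and clinical ratings decouple.

    Millisecond-scale speed irregularity is dominated by a
    severity-independent occasion-to-occasion component, while ratings
    track the slow severity; group separation survives through the
    completion-time pathway (advanced patients draw more slowly, which
    lowers their time-normalized score — the regime where the score
    *decreases* with severity).  This emulates the situation where the
    score measures high-frequency fluctuations invisible to visual
    clinical assessment.
    """
    return SimulationConfig(
        seed=seed,
        irregularity_gain=0.0005,
        occasion_irregularity_sd=0.005,
        completion_time_gain=0.15,
        rater_noise_sd=0.4,
    )


def severity_time_course(
    baseline_severity: float,
    pd_response: LevodopaResponse,
    times: Sequence[float],
    is_patient: bool = True,
) -> np.ndarray:
    """Latent severity at each scheduled time.

    Patients: ``severity(t) = max(0, baseline - effect(t))`` with the
    unimodal single-dose effect curve.  Healthy subjects (or
    ``is_patient=False``) get a constant trajectory at baseline.
    """
    t = np.asarray(times, dtype=float)
    if not is_patient:
        return np.full(t.shape, float(baseline_severity))
    return np.maximum(0.0, baseline_severity - pd_response.effect(t))


class _SpiralPath:
    """Arc-length parametrization of the pre-drawn Archimedean spiral."""

    def __init__(self, config: SimulationConfig) -> None:
        dev = config.device
        self.cx = dev.width_px / 2.0
        self.cy = dev.height_px / 2.0
        r_max = min(dev.width_px, dev.height_px) / 2.0 - config.margin_px
        theta_max = config.spiral_turns * 2.0 * math.pi
        self.b = r_max / theta_max
        theta = np.linspace(0.0, theta_max, 4096)
        # dl = sqrt(r^2 + (dr/dtheta)^2) dtheta with r = b*theta
        dl = self.b * np.sqrt(theta**2 + 1.0)
        arclen = np.concatenate(([0.0], np.cumsum((dl[1:] + dl[:-1]) / 2.0 * np.diff(theta))))
        self.theta = theta
        self.arclen = arclen
        self.total_length = float(arclen[-1])

    def position(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Screen position after drawing path length ``s`` from the center."""
        th = np.interp(s, self.arclen, self.theta)
        r = self.b * th
        return self.cx + r * np.cos(th), self.cy + r * np.sin(th)


def _smooth_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited unit-variance noise: white Gaussian, lightly smoothed."""
    eps = rng.standard_normal(n + 2)
    kernel = np.array([0.25, 0.5, 0.25])
    sm = np.convolve(eps, kernel, mode="valid")
    sd = float(np.sqrt(np.sum(kernel**2)))
    return sm / sd


def render_trial(
    severity: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    trial_index: int = 1,
    path: "_SpiralPath | None" = None,
    amp_offset: float = 0.0,
) -> SpiralTrial:
    """Draw one spiral at the given latent severity.

    The pen traverses the Archimedean spiral center-out at instantaneous
    speed ``v0 * (1 + drift + amp * noise)`` where ``amp =
    irregularity_gain * severity + amp_offset`` (floored at 0); event
    timestamps have jittered inter-event intervals; total duration grows
    with severity through ``completion_time_gain``.  All samples stay on
    the spiral, hence within the screen bounds.
    """
    if severity < 0:
        raise ValueError(f"severity must be >= 0, got {severity}")
    path = path or _SpiralPath(config)
    duration_s = (
        config.trial_duration_s
        * (1.0 + config.completion_time_gain * severity)
        * (1.0 + config.trial_duration_jitter * rng.standard_normal())
    )
    duration_s = max(duration_s, 1.0)
    duration_ms = duration_s * 1000.0

    # event times: jittered inter-event intervals, first sample at t=0
    n_events = int(duration_ms / config.sample_interval_ms) + 2
    if config.sample_jitter_ms > 0:
        dts = config.sample_interval_ms + config.sample_jitter_ms * rng.standard_normal(n_events)
        dts = np.clip(dts, 1.0, None)
    else:
        dts = np.full(n_events, config.sample_interval_ms)
    t_ms = np.concatenate(([0.0], np.cumsum(dts)))
    t_ms = t_ms[t_ms <= duration_ms]
    if t_ms.size < 4:
        t_ms = np.linspace(0.0, duration_ms, 4)

    # instantaneous speed profile on the event grid
    amp = max(0.0, config.irregularity_gain * severity + amp_offset)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    drift = config.drift_amplitude * np.sin(
        2.0 * math.pi * config.drift_cycles * t_ms / duration_ms + phase
    )
    noise = amp * _smooth_noise(t_ms.size, rng) if amp > 0 else np.zeros(t_ms.size)
    modulation = np.clip(1.0 + drift + noise, 0.05, None)

    # advance along the arc; rescale so the spiral is completed exactly
    dt_s = np.diff(t_ms) / 1000.0
    step = modulation[:-1] * dt_s
    s = np.concatenate(([0.0], np.cumsum(step)))
    s *= path.total_length / s[-1]
    x, y = path.position(s)
    return SpiralTrial(
        x=x, y=y, t_ms=t_ms, trial_index=trial_index, device=config.device
    )


def ratings_from_severity(
    severity: np.ndarray,
    effect: np.ndarray,
    effect_lagged: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    baseline_severity: float,
    n_raters: int = 3,
) -> list[dict[str, float]]:
    """Mean clinical ratings (three simulated raters) per occasion.

    The six UPDRS items are a clipped linear map of slow severity (the
    per-item slopes are fixed multipliers around ``rating_slope``), each
    rater adds independent Gaussian noise and clips to [0, 4]; the
    reported value is the rater mean.  Dyskinesia instead follows the
    lagged medication effect scaled by baseline severity — it peaks at
    On-with-dyskinesia, when the effect is maximal, not when severity is.
    """
    item_scales = {
        "updrs23": 1.00, "updrs25": 0.95, "updrs26": 0.90,
        "updrs27": 0.85, "updrs29": 0.90, "updrs31": 1.05,
    }
    out: list[dict[str, float]] = []
    for sev, eff, eff_lag in zip(severity, effect, effect_lagged):
        ratings: dict[str, float] = {}
        for item, scale in item_scales.items():
            true_value = np.clip(
                scale * config.rating_slope * (sev - config.rating_floor), 0.0, 4.0
            )
            raters = np.clip(
                true_value + config.rater_noise_sd * rng.standard_normal(n_raters),
                0.0,
                4.0,
            )
            ratings[item] = float(np.mean(raters))
        dys_true = np.clip(
            config.dys_gain * baseline_severity * eff_lag - 0.2, 0.0, 4.0
        )
        raters = np.clip(
            dys_true + config.rater_noise_sd * rng.standard_normal(n_raters), 0.0, 4.0
        )
        ratings["dys"] = float(np.mean(raters))
        out.append(ratings)
    return out


def _dropout_cutoffs(n_patients: int) -> list[float]:
    """Last observed occasion time per patient, reproducing the study's
    attrition counts when n_patients == 19 (scaled proportionally otherwise)."""
    times = sorted(DROPOUT_COUNTS)
    cutoffs: list[float] = []
    counts = {t: DROPOUT_COUNTS[t] for t in times}
    if n_patients != 19:
        counts = {
            t: int(round(c * n_patients / 19.0)) for t, c in counts.items()
        }
        counts[times[0]] = n_patients
    prev = n_patients
    for idx, t in enumerate(times):
        c = min(counts[t], prev)
        drop = prev - c
        cutoff_time = times[idx - 1] if idx > 0 else PATIENT_SCHEDULE[1]
        cutoffs.extend([cutoff_time] * drop)
        prev = c
    cutoffs.extend([times[-1]] * prev)
    return cutoffs  # length n_patients; order = assignment order


def simulate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate a full synthetic cohort (deterministic for a fixed seed).

    Patients (ids ``P01..``, groups early/intermediate/advanced in that
    order) get the 15-point dose schedule with ratings; healthy controls
    (``H01..``) get the 8-point schedule and no ratings.  Each occasion
    has exactly 3 trials unless dropout truncates the tail of a
    patient's schedule.
    """
    rng = np.random.default_rng(config.seed)
    path = _SpiralPath(config)
    records: list[SubjectRecord] = []

    group_sizes = [
        ("early", config.n_early),
        ("intermediate", config.n_intermediate),
        ("advanced", config.n_advanced),
    ]
    patient_groups = [g for g, n in group_sizes for _ in range(n)]
    cutoffs = (
        _dropout_cutoffs(config.n_patients)
        if config.dropout and config.n_patients
        else [PATIENT_SCHEDULE[-1]] * config.n_patients
    )

    n_male_pat = int(round(config.male_fraction_patient * config.n_patients))
    pat_genders = ["male"] * n_male_pat + ["female"] * (config.n_patients - n_male_pat)
    rng.shuffle(pat_genders)
    n_male_hc = int(round(config.male_fraction_healthy * config.n_healthy))
    hc_genders = ["male"] * n_male_hc + ["female"] * (config.n_healthy - n_male_hc)
    rng.shuffle(hc_genders)

    for i, group in enumerate(patient_groups):
        subject_id = f"P{i + 1:02d}"
        age = float(config.age_mean_patient + config.age_sd_patient * rng.standard_normal())
        base_sev = max(
            0.05,
            config.severity_scale[group] + config.severity_sd * rng.standard_normal(),
        )
        if group == "early":
            years = float(rng.uniform(0.5, 5.0))
        elif group == "intermediate":
            years = float(rng.uniform(5.0, 15.0))
        else:
            years = float(rng.uniform(8.0, 20.0))
        times = np.array([t for t in PATIENT_SCHEDULE if t <= cutoffs[i]])
        sev_traj = severity_time_course(base_sev, config.pd_response, times)
        eff = config.pd_response.effect(times)
        eff_lag = config.pd_response.effect(times - config.dys_lag_min)
        ratings = ratings_from_severity(
            sev_traj, eff, eff_lag, config, rng, baseline_severity=base_sev
        )
        occasions: list[TestOccasion] = []
        for k, minutes in enumerate(times):
            occ_sev = max(
                0.0, sev_traj[k] + config.occasion_severity_sd * rng.standard_normal()
            )
            amp_offset = (
                config.occasion_irregularity_sd * rng.standard_normal()
                if config.occasion_irregularity_sd > 0
                else 0.0
            )
            trials = [
                render_trial(occ_sev, config, rng, trial_index=j + 1,
                             path=path, amp_offset=amp_offset)
                for j in range(3)
            ]
            occasions.append(
                TestOccasion(
                    minutes_from_dose=float(minutes),
                    trials=trials,
                    ratings=ratings[k],
                )
            )
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group=group,
                age=age,
                gender=pat_genders[i],
                occasions=occasions,
                years_on_levodopa=years,
            )
        )

    for i in range(config.n_healthy):
        subject_id = f"H{i + 1:02d}"
        age = float(config.age_mean_healthy + config.age_sd_healthy * rng.standard_normal())
        base_sev = max(
            0.05,
            config.severity_scale["healthy"]
            + config.severity_sd * rng.standard_normal(),
        )
        times = np.array(HEALTHY_SCHEDULE, dtype=float)
        sev_traj = severity_time_course(
            base_sev, config.pd_response, times, is_patient=False
        )
        occasions = []
        for k, minutes in enumerate(times):
            occ_sev = max(
                0.0, sev_traj[k] + config.occasion_severity_sd * rng.standard_normal()
            )
            amp_offset = (
                config.occasion_irregularity_sd * rng.standard_normal()
                if config.occasion_irregularity_sd > 0
                else 0.0
            )
            trials = [
                render_trial(occ_sev, config, rng, trial_index=j + 1,
                             path=path, amp_offset=amp_offset)
                for j in range(3)
            ]
            occasions.append(
                TestOccasion(minutes_from_dose=float(minutes), trials=trials)
            )
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group="healthy",
                age=age,
                gender=hc_genders[i],
                occasions=occasions,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Lightweight score-level generators for estimator calibration
# ---------------------------------------------------------------------------

def simulate_trial_triples(
    n_occasions: int,
    icc: float,
    seed: int,
    mean: float = 0.0,
    total_sd: float = 1.0,
) -> pd.DataFrame:
    """Occasion x 3-trial score matrix with a target intraclass correlation.

    Scores are ``occasion effect + trial noise`` with variances chosen so
    that between-occasion variance / total variance equals ``icc``.
    Returns a long DataFrame (occasion, trial, score) for reliability
    estimator checks.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must be in [0, 1), got {icc}")
    rng = np.random.default_rng(seed)
    sd_b = total_sd * math.sqrt(icc)
    sd_w = total_sd * math.sqrt(1.0 - icc)
    occ_eff = mean + sd_b * rng.standard_normal(n_occasions)
    scores = occ_eff[:, None] + sd_w * rng.standard_normal((n_occasions, 3))
    return pd.DataFrame(
        {
            "occasion": np.repeat(np.arange(n_occasions), 3),
            "trial": np.tile([1, 2, 3], n_occasions),
            "score": scores.ravel(),
        }
    )


def simulate_score_table(
    seed: int,
    n_per_group: dict[str, int] | None = None,
    group_shift: dict[str, float] | None = None,
    age_effect: float = 0.0,
    subject_sd: float = 0.5,
    resid_sd: float = 1.0,
    baseline_mean: float = 5.0,
) -> pd.DataFrame:
    """Occasion-level TIS table generated directly at the score level.

    Bypasses trial rendering: each subject gets a random intercept
    (``subject_sd``) and each occasion i.i.d. residual noise
    (``resid_sd``); ``group_shift`` adds a fixed offset per group (in
    the same units as ``resid_sd``, so a shift of 1.5 with resid_sd=1 is
    1.5 residual SDs).  Used to calibrate the group-contrast model's
    error rates and power independently of the drawing model.
    """
    n_per_group = n_per_group or {
        "healthy": 22, "early": 7, "intermediate": 8, "advanced": 4,
    }
    group_shift = group_shift or {}
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, n in n_per_group.items():
        schedule = HEALTHY_SCHEDULE if group == "healthy" else PATIENT_SCHEDULE
        age_mean = 64.2 if group == "healthy" else 71.4
        age_sd = 7.4 if group == "healthy" else 6.3
        for _ in range(n):
            sid += 1
            age = age_mean + age_sd * rng.standard_normal()
            intercept = (
                baseline_mean
                + group_shift.get(group, 0.0)
                + age_effect * (age - 67.0)
                + subject_sd * rng.standard_normal()
            )
            for minutes in schedule:
                rows.append(
                    {
                        "subject_id": f"S{sid:03d}",
                        "group": group,
                        "age": age,
                        "gender": "male" if rng.random() < 0.7 else "female",
                        "occasion_minutes": float(minutes),
                        "occasion_tis": intercept + resid_sd * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)
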