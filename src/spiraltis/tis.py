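"""Temporal Irregularity Score: approximate entropy of the drawing-speed signal.

The score of one spiral trial is built in three steps:

1. *Drawing speed*: Euclidean pixel displacement between consecutive
   touch samples divided by the elapsed time in seconds,

       DS_i = sqrt((x_{i+1}-x_i)^2 + (y_{i+1}-y_i)^2) / (t_{i+1}-t_i),

   computed after halving the event rate (see
   :func:`spiraltis.io.downsample_every_second`).
2. *Approximate entropy* (ApEn) of the speed series: with Phi^m(r) the
   average over window starts i of log C_i^m(r), where C_i^m(r) is the
   fraction of length-m windows within tolerance r of window i,

       ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r).

   Defaults follow the standard regularity-statistic convention:
   Chebyshev window distance, self-matches included, natural log,
   m = 2 and r = 0.2 x SD of the trial's own speed series.
3. *Time normalization*: TIS = ApEn / completion time (s).  Dividing by
   completion time stabilizes the score across subjects who draw at
   very different paces; per test occasion the mean TIS over the (up
   to) three trials is the analysis value.

Higher TIS means more millisecond-scale irregularity in drawing speed
per second of drawing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, TrialValidationError
from .io import (
    RATING_SCALES,
    SpiralTrial,
    SubjectRecord,
    TestOccasion,
    downsample_every_second,
    require_valid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ApEnParams",
    "SpeedSignal",
    "TrialScore",
    "TISResult",
    "drawing_speed",
    "correlation_integral",
    "apen",
    "tis_score",
    "occasion_tis",
    "score_cohort",
    "parameter_grid_search",
]


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of the ApEn/TIS computation.

    m
        Embedding window length (>= 1).
    r_fraction
        Filter level as a fraction of the speed signal's standard
        deviation (> 0).
    distance
        Vector distance between embedding windows: ``"chebyshev"``
        (max coordinate difference, the classical convention) or
        ``"euclidean"``.
    self_match
        Whether window i counts itself as a match (classical ApEn: yes;
        guarantees C_i^m(r) > 0 so the log is always defined).
    downsample
        Apply the keep-every-second-sample rule before computing speed.
    r_scope
        ``"trial"`` scales r by the SD of each trial's own speed series;
        ``"cohort"`` uses a caller-supplied global SD (see
        :func:`score_cohort`).
    """

    m: int = 2
    r_fraction: float = 0.2
    distance: Literal["chebyshev", "euclidean"] = "chebyshev"
    self_match: bool = True
    downsample: bool = True
    r_scope: Literal["trial", "cohort"] = "trial"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r_fraction <= 0:
            raise ValueError(f"r_fraction must be > 0, got {self.r_fraction}")


@dataclass
class SpeedSignal:
    """Drawing-speed series (px/s) derived from one trial."""

    values: np.ndarray
    trial_index: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size

    @property
    def sd(self) -> float:
        return float(np.std(self.values))


@dataclass(frozen=True)
class TrialScore:
    apen: float
    completion_time_s: float
    tis: float
    trial_index: int = 1


@dataclass
class TISResult:
    """Per-trial scores and their occasion-level mean."""

    per_trial: list[TrialScore]
    occasion_tis: float  # NaN when no trial was scorable
    n_excluded: int = 0


def drawing_speed(trial: SpiralTrial, validate: bool = True) -> SpeedSignal:
    """Speed between consecutive samples: pixel displacement over seconds.

    The output has one value per consecutive sample pair (length n-1).
    Timestamps are in milliseconds; speeds are in px/s.
    """
    if len(trial) < 2:
        raise DegenerateInputError(
            f"drawing speed needs >= 2 samples, got {len(trial)}"
        )
    if validate:
        require_valid(trial)
    dt_s = np.diff(trial.t_ms) / 1000.0
    if np.any(dt_s <= 0):
        raise TrialValidationError("timestamps must be strictly increasing")
    disp = np.hypot(np.diff(trial.x), np.diff(trial.y))
    return SpeedSignal(values=disp / dt_s, trial_index=trial.trial_index)


def _embed(values: np.ndarray, m: int) -> np.ndarray:
    """All length-m windows of the series as rows, shape (n - m + 1, m)."""
    n = values.size
    if n < m:
        raise DegenerateInputError(f"series of length {n} has no windows of length {m}")
    return np.lib.stride_tricks.sliding_window_view(values, m)


def _window_distances(windows: np.ndarray, distance: str) -> np.ndarray:
    diff = windows[:, None, :] - windows[None, :, :]
    if distance == "chebyshev":
        return np.max(np.abs(diff), axis=-1)
    if distance == "euclidean":
        return np.sqrt(np.sum(diff * diff, axis=-1))
    raise ValueError(f"unknown distance {distance!r}")


def correlation_integral(
    series: SpeedSignal | Sequence[float] | np.ndarray,
    i: int,
    m: int,
    r: float,
    distance: str = "chebyshev",
    self_match: bool = True,
) -> float:
    """C_i^m(r): fraction of length-m windows within distance r of window i.

    ``i`` is the 0-based start index of the reference window,
    ``0 <= i <= n - m``.  ``r`` is an absolute tolerance.  With
    self-matching (default) the result is always >= 1 / (n - m + 1).
    """
    values = series.values if isinstance(series, SpeedSignal) else np.asarray(series, float)
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    windows = _embed(values, m)
    n_windows = windows.shape[0]
    if not 0 <= i < n_windows:
        raise IndexError(f"window start {i} outside [0, {n_windows - 1}]")
    diff = np.abs(windows - windows[i])
    if distance == "chebyshev":
        d = diff.max(axis=1)
    elif distance == "euclidean":
        d = np.sqrt((diff * diff).sum(axis=1))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    within = d <= r
    if not self_match:
        within[i] = False
        return float(np.count_nonzero(within)) / (n_windows - 1) if n_windows > 1 else 0.0
    return float(np.count_nonzero(within)) / n_windows


def _phi(values: np.ndarray, m: int, r: float, distance: str, self_match: bool) -> float:
    windows = _embed(values, m)
    d = _window_distances(windows, distance)
    counts = np.count_nonzero(d <= r, axis=1).astype(float)
    if not self_match:
        counts -= 1.0
        if np.any(counts <= 0):
            raise DegenerateInputError(
                "a window has no neighbours within r; cannot take log "
                "(use self_match=True)"
            )
        c = counts / (windows.shape[0] - 1)
    else:
        c = counts / windows.shape[0]
    return float(np.mean(np.log(c)))


_NEG_TOL = 1e-12


def apen(
    series: SpeedSignal | Sequence[float] | np.ndarray,
    params: ApEnParams = ApEnParams(),
    r_absolute: float | None = None,
) -> float:
    """Approximate entropy (nats) of a series.

    The tolerance is ``params.r_fraction`` times the series SD unless an
    absolute ``r_absolute`` is supplied.  A zero-variance series returns
    0.0 by convention (a constant signal is maximally regular).  Needs
    ``n >= m + 2`` so that both Phi terms have at least one window.
    Tiny negative floating-point results (within 1e-12) are clamped to 0.
    """
    values = series.values if isinstance(series, SpeedSignal) else np.asarray(series, float)
    n = values.size
    if n < params.m + 2:
        raise DegenerateInputError(
            f"ApEn with m={params.m} needs at least {params.m + 2} samples, got {n}"
        )
    if r_absolute is not None:
        r = float(r_absolute)
        if r <= 0:
            raise ValueError(f"absolute r must be > 0, got {r}")
    else:
        sd = float(np.std(values))
        if sd == 0.0:
            return 0.0
        r = params.r_fraction * sd
    result = _phi(values, params.m, r, params.distance, params.self_match) - _phi(
        values, params.m + 1, r, params.distance, params.self_match
    )
    if -_NEG_TOL <= result < 0.0:
        # numerical round-off on an exactly-regular series
        result = 0.0
    elif result < 0.0:
        # genuinely negative small-sample estimates are reported as-is;
        # the statistic's finite-n bias can cross zero for short series
        logger.debug("negative ApEn %.3g at n=%d, m=%d", result, n, params.m)
    return result


def tis_score(
    trial: SpiralTrial,
    params: ApEnParams = ApEnParams(),
    r_absolute: float | None = None,
) -> TrialScore:
    """Score one trial: ApEn of its speed signal divided by completion time.

    Down-sampling (when enabled) is applied first; completion time is
    the elapsed time between the first and last sample actually used,
    in seconds, so the identity ``tis * completion_time == apen`` holds
    exactly on the scored series.
    """
    require_valid(trial)
    used = downsample_every_second(trial) if params.downsample else trial
    completion = used.duration_s
    if completion <= 0:
        raise TrialValidationError(
            f"completion time {completion} s is not positive"
        )
    speed = drawing_speed(used, validate=False)
    value = apen(speed, params, r_absolute=r_absolute)
    return TrialScore(
        apen=value,
        completion_time_s=completion,
        tis=value / completion,
        trial_index=trial.trial_index,
    )


def occasion_tis(
    occasion: TestOccasion,
    params: ApEnParams = ApEnParams(),
    r_absolute: float | None = None,
) -> TISResult:
    """Score every scorable trial of an occasion and average the TIS values.

    Trials that fail validation or are too short are excluded (and
    logged), not fatal; with zero scorable trials the occasion-level
    score is NaN (a missing-data marker).
    """
    per_trial: list[TrialScore] = []
    n_excluded = 0
    for trial in occasion.trials:
        try:
            per_trial.append(tis_score(trial, params, r_absolute=r_absolute))
        except (TrialValidationError, DegenerateInputError) as exc:
            n_excluded += 1
            logger.warning(
                "excluding trial %d at %s min: %s",
                trial.trial_index,
                occasion.minutes_from_dose,
                exc,
            )
    if per_trial:
        mean_tis = float(np.mean([s.tis for s in per_trial]))
    else:
        mean_tis = math.nan
    return TISResult(per_trial=per_trial, occasion_tis=mean_tis, n_excluded=n_excluded)


def score_cohort(
    records: Iterable[SubjectRecord],
    params: ApEnParams = ApEnParams(),
) -> pd.DataFrame:
    """Score a cohort: one row per (subject, occasion).

    Columns: design variables, per-trial ``apen_t{k}``,
    ``completion_s_t{k}``, ``tis_t{k}`` (k = 1..3, NaN where the trial is
    absent or unscorable), the occasion-level mean ``occasion_tis``, and
    any rating scales present.

    With ``params.r_scope == "cohort"`` the ApEn tolerance is fixed at
    ``r_fraction`` times the pooled SD of all trial speed series in the
    cohort, instead of each trial's own SD.
    """
    records = list(records)
    r_absolute: float | None = None
    if params.r_scope == "cohort":
        pooled: list[np.ndarray] = []
        for rec in records:
            for occ in rec.occasions:
                for trial in occ.trials:
                    used = downsample_every_second(trial) if params.downsample else trial
                    try:
                        pooled.append(drawing_speed(used, validate=False).values)
                    except (TrialValidationError, DegenerateInputError):
                        continue
        if not pooled:
            raise DegenerateInputError("no scorable trials in cohort")
        r_absolute = params.r_fraction * float(np.std(np.concatenate(pooled)))

    rows: list[dict[str, object]] = []
    for rec in records:
        for occ in rec.occasions:
            result = occasion_tis(occ, params, r_absolute=r_absolute)
            row: dict[str, object] = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": rec.age,
                "gender": rec.gender,
                "occasion_minutes": occ.minutes_from_dose,
                "occasion_tis": result.occasion_tis,
            }
            scored = {s.trial_index: s for s in result.per_trial}
            for k in (1, 2, 3):
                score = scored.get(k)
                row[f"apen_t{k}"] = score.apen if score else math.nan
                row[f"completion_s_t{k}"] = score.completion_time_s if score else math.nan
                row[f"tis_t{k}"] = score.tis if score else math.nan
            if occ.ratings:
                for scale in RATING_SCALES:
                    if scale in occ.ratings:
                        row[scale] = occ.ratings[scale]
            rows.append(row)
    return pd.DataFrame(rows)


def parameter_grid_search(
    records: Sequence[SubjectRecord],
    m_values: Sequence[int] = (2, 4),
    r_fractions: Sequence[float] = (0.1, 0.2),
    weights: dict[str, float] | None = None,
    base_params: ApEnParams = ApEnParams(),
    baseline_minutes: float = -20.0,
) -> pd.DataFrame:
    """Evaluate ApEn parameter configurations on four clinimetric criteria.

    For each (m, r_fraction) on the grid the cohort is re-scored and four
    criteria are computed: test-retest ICC across the three trials, the
    maximum patient effect size over post-baseline timepoints, the mean
    absolute Pearson correlation between TIS and the rating scales, and
    the magnitude (|z|) of the advanced-vs-healthy group contrast.
    Configurations are ranked by the weighted sum of the standardized
    criteria (equal weights by default); an incomputable criterion is
    recorded as NaN and ignored in that configuration's score.
    """
    from . import clinimetrics as cl

    weights = weights or {
        "icc": 1.0,
        "max_effect_size": 1.0,
        "mean_abs_rating_corr": 1.0,
        "separation": 1.0,
    }
    rows = []
    for m in m_values:
        for r_frac in r_fractions:
            params = replace(base_params, m=m, r_fraction=r_frac)
            scored = score_cohort(records, params)
            row: dict[str, float] = {"m": float(m), "r_fraction": float(r_frac)}
            try:
                row["icc"] = cl.test_retest_icc(scored).estimate
            except Exception:
                row["icc"] = math.nan
            try:
                effects = cl.timepoint_effect_sizes(
                    scored, baseline_minutes=baseline_minutes
                )
                patient = effects[effects["cohort"] == "patients"]
                row["max_effect_size"] = float(patient["effect_size"].max())
            except Exception:
                row["max_effect_size"] = math.nan
            try:
                corr = cl.clinical_correlations(scored)
                row["mean_abs_rating_corr"] = float(corr["r"].abs().mean())
            except Exception:
                row["mean_abs_rating_corr"] = math.nan
            try:
                contrasts = cl.fit_group_lme(scored)
                adv = contrasts.loc[contrasts["contrast"] == "advanced"].iloc[0]
                row["separation"] = abs(float(adv["coef"]) / float(adv["se"]))
            except Exception:
                row["separation"] = math.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    criteria = ["icc", "max_effect_size", "mean_abs_rating_corr", "separation"]
    score = np.zeros(len(table))
    for crit in criteria:
        col = table[crit].to_numpy(dtype=float)
        sd = np.nanstd(col)
        z = (col - np.nanmean(col)) / sd if sd > 0 else np.zeros_like(col)
        z = np.nan_to_num(z, nan=0.0)
        score += weights.get(crit, 0.0) * z
    table["score"] = score
    table["rank"] = (
        table["score"].rank(ascending=False, method="min").astype(int)
    )
    return table.sort_values("rank", kind="stable").reset_index(drop=True)
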