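"""Clinimetric evaluation of the occasion-level score table.

Implements the study-style statistical battery on a scored cohort
(one row per subject x occasion, see :func:`spiraltis.tis.score_cohort`):

* group contrasts (early / intermediate / advanced / all patients, each
  vs healthy) from linear mixed-effects models with a subject random
  intercept and age as covariate, fitted by REML;
* test-retest reliability of the score across the three trials of an
  occasion (intraclass correlation);
* a Fisher exact test on the patients-vs-healthy gender table;
* per-timepoint treatment-response effect sizes: for each post-baseline
  timepoint, a one-way ANOVA between the baseline and timepoint scores
  of the subjects observed at both, summarized as eta-squared;
* Pearson correlations between the score and each mean clinical rating
  scale.

Everything is collected into a serializable :class:`ClinimetricReport`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.formula.api as smf

from .errors import DegenerateInputError
from .io import RATING_SCALES

__all__ = [
    "ICCResult",
    "ClinimetricReport",
    "fit_group_lme",
    "test_retest_icc",
    "gender_fisher_test",
    "timepoint_effect_sizes",
    "clinical_correlations",
    "build_report",
    "evaluate_cohort",
]

PATIENT_GROUPS = ("early", "intermediate", "advanced")


def _clean(df: pd.DataFrame) -> pd.DataFrame:
    return df.dropna(subset=["occasion_tis"]).copy()


def fit_group_lme(scored: pd.DataFrame) -> pd.DataFrame:
    """Group contrasts on occasion-level scores, each group vs healthy.

    Fits ``occasion_tis ~ group + age`` with a subject random intercept
    by restricted maximum likelihood, healthy as the reference level, to
    obtain the early/intermediate/advanced contrasts; a second fit with
    a binary patient indicator gives the pooled all-patients contrast.
    Returns a DataFrame with columns ``contrast, coef, se, p, converged``.
    If a fit is singular or fails, the ordinary-least-squares estimate
    is reported instead with ``converged=False``.
    """
    data = _clean(scored)
    if data["group"].nunique() < 2:
        raise DegenerateInputError("need at least 2 groups for contrasts")
    present = [g for g in PATIENT_GROUPS if g in set(data["group"])]
    age_varies = data["age"].nunique() > 1
    age_term = " + age" if age_varies else ""

    rows: list[dict[str, object]] = []

    def _fit(formula: str, frame: pd.DataFrame, terms: list[tuple[str, str]]) -> None:
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm(formula, frame, groups=frame["subject_id"]).fit(reml=True)
                if not fit.converged:
                    converged = False
            except Exception:
                fit = smf.ols(formula, frame).fit()
                converged = False
        for term, label in terms:
            if term in fit.params.index:
                rows.append(
                    {
                        "contrast": label,
                        "coef": float(fit.params[term]),
                        "se": float(fit.bse[term]),
                        "p": float(fit.pvalues[term]),
                        "converged": converged,
                    }
                )
            else:
                rows.append(
                    {"contrast": label, "coef": math.nan, "se": math.nan,
                     "p": math.nan, "converged": False}
                )

    formula = f"occasion_tis ~ C(group, Treatment('healthy')){age_term}"
    terms = [
        (f"C(group, Treatment('healthy'))[T.{g}]", g) for g in present
    ]
    if "healthy" in set(data["group"]) and present:
        _fit(formula, data, terms)

    pooled = data.copy()
    pooled["patient"] = (pooled["group"] != "healthy").astype(int)
    if pooled["patient"].nunique() == 2:
        _fit(f"occasion_tis ~ patient{age_term}", pooled, [("patient", "all_patients")])

    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    form: str
    n_occasions: int


_ICC_TYPE = {
    "oneway-random": "ICC(1,1)",
    "twoway-random-agreement": "ICC(A,1)",
    "twoway-consistency": "ICC(C,1)",
}


def test_retest_icc(
    scored: pd.DataFrame,
    form: Literal["twoway-consistency", "twoway-random-agreement", "oneway-random"] = "twoway-consistency",
    complete_only: bool = True,
) -> ICCResult:
    """Test-retest reliability of the trial-level score across the 3 trials.

    Builds the grand occasion x trial matrix (every occasion of every
    subject is a target, the three repeated trials are the "raters") and
    computes a single-measure ICC.  Default form: two-way mixed effects,
    consistency (the three repeats are a fixed set), ICC(3,1).
    ``complete_only`` keeps occasions with all three trials scored.
    """
    cols = ["tis_t1", "tis_t2", "tis_t3"]
    missing = [c for c in cols if c not in scored.columns]
    if missing:
        raise DegenerateInputError(f"scored table lacks trial columns {missing}")
    wide = scored[cols].copy()
    if complete_only:
        wide = wide.dropna()
    else:
        wide = wide.dropna(thresh=2)
    if len(wide) < 2:
        raise DegenerateInputError(
            f"need >= 2 occasions with trial scores, got {len(wide)}"
        )
    long = wide.reset_index(drop=True).reset_index(names="occasion").melt(
        id_vars="occasion", var_name="trial", value_name="score"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long.dropna(), targets="occasion", raters="trial",
            ratings="score", nan_policy="omit",
        ).set_index("Type")
    row = table.loc[_ICC_TYPE[form]]
    ci = row["CI95%"] if "CI95%" in row.index else row["CI95"]
    return ICCResult(
        estimate=float(row["ICC"]),
        ci_lower=float(ci[0]),
        ci_upper=float(ci[1]),
        form=form,
        n_occasions=int(len(wide)),
    )


def gender_fisher_test(subjects: pd.DataFrame) -> tuple[float, float]:
    """Fisher exact test on the patients-vs-healthy x male/female table.

    ``subjects`` needs one row per subject with ``group`` and ``gender``
    columns (a scored table works: it is deduplicated on subject_id).
    Returns ``(odds_ratio, p_two_sided)``.
    """
    if "subject_id" in subjects.columns:
        subjects = subjects.drop_duplicates("subject_id")
    is_patient = subjects["group"] != "healthy"
    is_male = subjects["gender"] == "male"
    table = [
        [int((is_patient & is_male).sum()), int((is_patient & ~is_male).sum())],
        [int((~is_patient & is_male).sum()), int((~is_patient & ~is_male).sum())],
    ]
    if min(sum(r) for r in table) == 0:
        raise DegenerateInputError("cannot form a 2x2 gender table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def _eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """One-way ANOVA effect size between two samples: SS_between/SS_total."""
    grand = np.concatenate([a, b]).mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_total = float(((np.concatenate([a, b]) - grand) ** 2).sum())
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def _cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float(abs(b.mean() - a.mean()) / pooled) if pooled > 0 else 0.0


def timepoint_effect_sizes(
    scored: pd.DataFrame,
    baseline_minutes: float = -20.0,
    healthy_baseline_minutes: float = 0.0,
    kind: Literal["eta2", "cohen_d"] = "eta2",
    min_pairs: int = 2,
) -> pd.DataFrame:
    """Treatment-response effect size at each post-baseline timepoint.

    For each cohort (patients pooled; healthy) and each timepoint after
    its baseline occasion, restrict to subjects observed at both the
    baseline and that timepoint and fit a one-way ANOVA between the two
    sets of scores; report eta-squared (SS_effect / SS_total; or
    |Cohen's d| with ``kind="cohen_d"``).  Timepoints with fewer than
    ``min_pairs`` paired subjects are excluded.

    Returns columns ``cohort, occasion_minutes, effect_size, n_pairs``.
    """
    data = _clean(scored)
    rows = []
    for cohort, base_min in (
        ("patients", baseline_minutes),
        ("healthy", healthy_baseline_minutes),
    ):
        sub = data[
            data["group"].isin(PATIENT_GROUPS)
            if cohort == "patients"
            else (data["group"] == "healthy")
        ]
        if sub.empty:
            continue
        base = sub[sub["occasion_minutes"] == base_min].set_index("subject_id")[
            "occasion_tis"
        ]
        for minutes in sorted(sub["occasion_minutes"].unique()):
            if minutes <= base_min:
                continue
            tp = sub[sub["occasion_minutes"] == minutes].set_index("subject_id")[
                "occasion_tis"
            ]
            shared = base.index.intersection(tp.index)
            if len(shared) < min_pairs:
                continue
            a = base.loc[shared].to_numpy(dtype=float)
            b = tp.loc[shared].to_numpy(dtype=float)
            effect = _eta_squared(a, b) if kind == "eta2" else _cohen_d(a, b)
            rows.append(
                {
                    "cohort": cohort,
                    "occasion_minutes": float(minutes),
                    "effect_size": effect,
                    "n_pairs": int(len(shared)),
                }
            )
    return pd.DataFrame(rows, columns=["cohort", "occasion_minutes", "effect_size", "n_pairs"])


def clinical_correlations(
    scored: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Pearson correlation between the occasion score and each rating scale.

    Uses all patient occasions where both the score and the scale are
    present; scales with fewer than ``min_pairs`` pairs are skipped.
    Returns columns ``scale, r, p, n``.
    """
    data = _clean(scored)
    data = data[data["group"].isin(PATIENT_GROUPS)]
    rows = []
    for scale in RATING_SCALES:
        if scale not in data.columns:
            continue
        sub = data.dropna(subset=[scale])
        if len(sub) < min_pairs:
            continue
        r, p = stats.pearsonr(sub["occasion_tis"], sub[scale])
        rows.append({"scale": scale, "r": float(r), "p": float(p), "n": int(len(sub))})
    return pd.DataFrame(rows, columns=["scale", "r", "p", "n"])


@dataclass
class ClinimetricReport:
    """Structured results of the full battery; any section may be missing."""

    lme: list[dict] | None = None
    icc: dict | None = None
    gender_test: dict | None = None
    effect_sizes: list[dict] | None = None
    correlations: list[dict] | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "ClinimetricReport":
        try:
            data = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)

    def summary(self) -> str:
        lines = ["Clinimetric report", "=================="]
        if self.lme:
            lines.append("Group contrasts vs healthy (coef, p):")
            for row in self.lme:
                lines.append(
                    f"  {row['contrast']:>13}: {row['coef']:+.4g} (p={row['p']:.3g})"
                )
        else:
            lines.append("Group contrasts: missing")
        if self.icc:
            lines.append(
                f"Test-retest ICC ({self.icc['form']}): {self.icc['estimate']:.3f} "
                f"[{self.icc['ci_lower']:.3f}, {self.icc['ci_upper']:.3f}] "
                f"over {self.icc['n_occasions']} occasions"
            )
        else:
            lines.append("Test-retest ICC: missing")
        if self.gender_test:
            lines.append(
                f"Gender (Fisher exact): OR={self.gender_test['odds_ratio']:.3g}, "
                f"p={self.gender_test['p']:.3g}"
            )
        else:
            lines.append("Gender test: missing")
        if self.effect_sizes:
            pat = [e for e in self.effect_sizes if e["cohort"] == "patients"]
            if pat:
                best = max(pat, key=lambda e: e["effect_size"])
                lines.append(
                    f"Peak patient effect size: {best['effect_size']:.3f} "
                    f"at {best['occasion_minutes']:g} min"
                )
        else:
            lines.append("Effect sizes: missing")
        if self.correlations:
            lines.append("Score-rating Pearson r:")
            for row in self.correlations:
                lines.append(f"  {row['scale']:>8}: {row['r']:+.2f} (n={row['n']})")
        else:
            lines.append("Rating correlations: missing")
        return "\n".join(lines)


def build_report(
    lme: pd.DataFrame | None = None,
    icc: ICCResult | None = None,
    gender_test: tuple[float, float] | None = None,
    effect_sizes: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> ClinimetricReport:
    """Assemble analysis outputs into a serializable report."""
    return ClinimetricReport(
        lme=lme.to_dict("records") if lme is not None else None,
        icc=asdict(icc) if icc is not None else None,
        gender_test=(
            {"odds_ratio": gender_test[0], "p": gender_test[1]}
            if gender_test is not None
            else None
        ),
        effect_sizes=(
            effect_sizes.to_dict("records") if effect_sizes is not None else None
        ),
        correlations=(
            correlations.to_dict("records") if correlations is not None else None
        ),
        meta=meta or {},
    )


def evaluate_cohort(
    scored: pd.DataFrame,
    baseline_minutes: float = -20.0,
    icc_form: str = "twoway-consistency",
    effect_size_kind: str = "eta2",
) -> ClinimetricReport:
    """Run the full battery on a scored table; missing inputs skip sections."""
    lme = icc = gender = effects = corr = None
    try:
        lme = fit_group_lme(scored)
    except DegenerateInputError:
        pass
    try:
        icc = test_retest_icc(scored, form=icc_form)  # type: ignore[arg-type]
    except DegenerateInputError:
        pass
    try:
        gender = gender_fisher_test(scored)
    except (DegenerateInputError, KeyError):
        pass
    try:
        effects = timepoint_effect_sizes(
            scored, baseline_minutes=baseline_minutes, kind=effect_size_kind  # type: ignore[arg-type]
        )
        if effects.empty:
            effects = None
    except (DegenerateInputError, KeyError):
        pass
    try:
        corr = clinical_correlations(scored)
        if corr.empty:
            corr = None
    except (DegenerateInputError, KeyError):
        pass
    return build_report(
        lme=lme,
        icc=icc,
        gender_test=gender,
        effect_sizes=effects,
        correlations=corr,
        meta={
            "n_subjects": int(scored["subject_id"].nunique()),
            "n_occasions": int(len(scored)),
            "baseline_minutes": baseline_minutes,
            "icc_form": icc_form,
            "effect_size_kind": effect_size_kind,
        },
    )


def plot_report(report: ClinimetricReport, outdir: str) -> list[str]:
    """Render the group-contrast chart and effect-size curves to PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if report.lme:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        labels = [r["contrast"] for r in report.lme]
        coefs = [r["coef"] for r in report.lme]
        errs = [1.96 * r["se"] for r in report.lme]
        ax.errorbar(range(len(labels)), coefs, yerr=errs, fmt="o", capsize=4)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(range(len(labels)), labels, rotation=20)
        ax.set_ylabel("TIS contrast vs healthy")
        fig.tight_layout()
        path = out / "group_contrasts.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))

    if report.effect_sizes:
        fig, ax = plt.subplots(figsize=(5.5, 3.2))
        frame = pd.DataFrame(report.effect_sizes)
        for cohort, sub in frame.groupby("cohort"):
            ax.plot(sub["occasion_minutes"], sub["effect_size"], "o-", label=cohort)
        ax.set_xlabel("minutes from baseline/dose")
        ax.set_ylabel("effect size")
        ax.legend()
        fig.tight_layout()
        path = out / "effect_sizes.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
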