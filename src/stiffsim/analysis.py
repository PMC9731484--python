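"""Per-subject regression, group summaries and the strategy-text coder.

Each subject's ability to track simulated elbow stiffness is quantified by an
ordinary least-squares fit of their rating against the stiffness value E; the
coefficient of determination R^2 is the fraction of rating variance the
stiffness accounts for, and the slope is the rating change per N*m/rad.
Group-level summaries compare conditions with a one-way ANOVA on the
per-subject R^2 and slopes (conditions are between-subjects in Experiment 1)
and with pairwise paired t-tests on per-subject condition means (timing
conditions are within-subject in Experiment 2). Written strategy reports are
coded into four binary features by keyword criteria.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FitResult",
    "StrategyCode",
    "fit_subject",
    "fit_all_subjects",
    "summarize",
    "code_strategy",
    "STRATEGY_KEYWORDS",
]


@dataclass(frozen=True)
class FitResult:
    subject_id: int
    condition: str
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    n: int


def fit_subject(ratings: pd.DataFrame) -> FitResult:
    """OLS fit of rating on simulated elbow stiffness for one subject.

    Requires at least 3 trials spanning at least 2 distinct E values. A
    subject whose ratings never vary has zero regression sum of squares; by
    convention their R^2 (and Pearson r) is reported as 0.
    """
    if ratings["subject_id"].nunique() != 1:
        raise ValueError("fit_subject expects a single subject's trials")
    E = ratings["E"].to_numpy(dtype=float)
    y = ratings["rating"].to_numpy(dtype=float)
    if len(E) < 3:
        raise ValueError("need at least 3 trials")
    if np.unique(E).size < 2:
        raise ValueError("need at least 2 distinct E values")

    if np.ptp(y) == 0.0:
        # constant ratings: the fitted line is exactly flat at the rating
        slope, intercept = 0.0, float(y[0])
    else:
        slope, intercept = np.polyfit(E, y, 1)
    yhat = slope * E + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_reg = float(np.sum((yhat - y.mean()) ** 2))
    if ss_reg <= 1e-14 * max(1.0, ss_tot) or ss_tot == 0.0:
        r2, r = 0.0, 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        r = float(np.corrcoef(E, y)[0, 1])
    cond = ratings["condition"].iloc[0] if ratings["condition"].nunique() == 1 else "mixed"
    return FitResult(
        subject_id=int(ratings["subject_id"].iloc[0]),
        condition=cond,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        pearson_r=r,
        n=len(E),
    )


def fit_all_subjects(dataset: pd.DataFrame) -> pd.DataFrame:
    """One FitResult row per subject."""
    fits = [
        asdict(fit_subject(grp)) for _, grp in dataset.groupby("subject_id", sort=True)
    ]
    return pd.DataFrame(fits)


def _mean_2se(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    n = values.size
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {"mean": float(values.mean()), "two_se": 2 * se, "n": int(n)}


def summarize(dataset: pd.DataFrame, fits: pd.DataFrame | None = None) -> dict:
    """Group report: rating curves, fit summaries, ANOVA and paired contrasts.

    Returns a JSON-serializable dict with, per condition, the mean rating
    (+/- 2 SE) at each stiffness level and the mean R^2 and slope of the
    per-subject fits; a one-way ANOVA (F, p) of R^2 and of slope across
    conditions when at least two conditions have two or more subjects; and,
    for within-subject (Experiment 2 style) data, per-condition mean ratings
    with all pairwise paired t-tests on subject means.
    """
    experiment = int(dataset["experiment"].iloc[0]) if "experiment" in dataset else 1
    report: dict = {"experiment": experiment, "conditions": {}}

    for cond, grp in dataset.groupby("condition", sort=True):
        by_E = {
            float(E): _mean_2se(sub["rating"].to_numpy())
            for E, sub in grp.groupby("E", sort=True)
        }
        report["conditions"][cond] = {"ratings_by_E": by_E}

    within_subject = (
        dataset.groupby("subject_id")["condition"].nunique().max() > 1
    )

    if not within_subject:
        if fits is None:
            fits = fit_all_subjects(dataset)
        groups_r2, groups_slope = [], []
        for cond, grp in fits.groupby("condition", sort=True):
            report["conditions"].setdefault(cond, {})
            report["conditions"][cond]["r_squared"] = _mean_2se(grp["r_squared"])
            report["conditions"][cond]["slope"] = _mean_2se(grp["slope"])
            groups_r2.append(grp["r_squared"].to_numpy())
            groups_slope.append(grp["slope"].to_numpy())
        if len(groups_r2) >= 2:
            # the between-condition comparison needs >= 2 subjects per group
            if any(len(g) < 2 for g in groups_r2):
                raise ValueError("ANOVA needs >= 2 subjects in >= 2 conditions")
            f_r2, p_r2 = stats.f_oneway(*groups_r2)
            f_sl, p_sl = stats.f_oneway(*groups_slope)
            report["anova_r_squared"] = {"F": float(f_r2), "p": float(p_r2)}
            report["anova_slope"] = {"F": float(f_sl), "p": float(p_sl)}
    else:
        # within-subject design: per-condition subject means and paired tests
        subj_means = (
            dataset.pivot_table(
                index="subject_id", columns="condition", values="rating", aggfunc="mean"
            )
            .sort_index()
        )
        report["condition_means"] = {
            cond: _mean_2se(subj_means[cond].to_numpy()) for cond in subj_means.columns
        }
        pairs = {}
        conds = list(subj_means.columns)
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                diff = subj_means[a].to_numpy() - subj_means[b].to_numpy()
                if np.allclose(diff, 0.0):
                    t, p = 0.0, 1.0  # no paired difference at all
                else:
                    t, p = stats.ttest_rel(subj_means[a], subj_means[b])
                pairs[f"{a} vs {b}"] = {"t": float(t), "p": float(p)}
        report["paired_t_tests"] = pairs
    return report


# Keyword criteria used to code written strategy reports. "angle" counts as
# both path information and joint motion; picture-based criteria cannot be
# applied to text and are out of scope.
STRATEGY_KEYWORDS = {
    "path_info": ("distance", "displacement", "range of motion", "angle"),
    "temporal_info": ("speed", "rate", "acceleration", "jerk", "smooth"),
    "joint_motion": ("joint", "shoulder", "elbow", "angle"),
    "endpoint_motion": ("endpoint", "hand"),
}


@dataclass(frozen=True)
class StrategyCode:
    path_info: bool
    temporal_info: bool
    joint_motion: bool
    endpoint_motion: bool


def code_strategy(text: str) -> StrategyCode:
    """Code a written strategy into four binary motion features.

    Matching is case-insensitive on whole words (or whole phrases), so
    "accurate" does not trigger "rate" and "hand's" still triggers "hand".
    """
    if not text or not text.strip():
        raise ValueError("strategy text must be nonempty")
    low = text.lower()

    def hit(keywords: tuple[str, ...]) -> bool:
        return any(
            re.search(r"\b" + re.escape(kw) + r"\b", low) is not None
            for kw in keywords
        )

    return StrategyCode(**{feat: hit(kws) for feat, kws in STRATEGY_KEYWORDS.items()})
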