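"""Synthetic Likert raters emulating the two perception experiments.

The experiments show each subject a set of arm motions (six elbow-stiffness
levels in Experiment 1, four timing conditions of one path in Experiment 2),
five times each in randomized blocks, and collect a 1-7 stiffness rating per
trial. No human data are modeled here; instead each synthetic subject maps a
single driving motion feature linearly onto the rating scale and then passes
it through the two response distortions the Likert instrument is known for:

* quantization — the continuous internal estimate is forced onto a discrete
  scale, adding rounding noise whose variance shrinks as the number of scale
  options grows;
* central-tendency bias — raters avoid the scale extremes, modeled as affine
  shrinkage of the internal estimate toward the scale midpoint (4 on the
  default 7-point scale) before quantization.

An optional ``temporal_penalty`` raises the rating of every non-veridical
timing condition, the structure observed in Experiment 2 (veridical motion
judged least stiff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectModel",
    "build_design",
    "generate_ratings",
    "quantize_rating",
]

SCALE_LO, SCALE_HI = 1.0, 7.0
SCALE_MID = 0.5 * (SCALE_LO + SCALE_HI)


@dataclass(frozen=True)
class SubjectModel:
    """Response model of one synthetic rater.

    ``driving_feature`` names a column of the feature table (or ``"E"`` to
    rate the simulated stiffness directly); a leading ``-`` negates it, so
    the default ``-elbow_rom`` means "smaller elbow excursion looks stiffer".
    ``gain`` is in rating units per standard deviation of the driving feature
    across the subject's stimulus set. ``noise_sd`` is trial-to-trial latent
    noise in rating units, applied before quantization. ``central_tendency``
    in [0, 1] shrinks the latent rating toward the scale midpoint (1 pins
    every response at the midpoint). ``n_options`` is the number of scale
    levels spread over [1, 7] (7 gives the integer Likert scale).
    """

    gain: float = 2.0
    intercept: float = SCALE_MID
    noise_sd: float = 1.0
    central_tendency: float = 0.15
    driving_feature: str = "-elbow_rom"
    temporal_penalty: float = 0.0
    n_options: int = 7

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.central_tendency <= 1:
            raise ValueError("central_tendency must lie in [0, 1]")
        if self.temporal_penalty < 0:
            raise ValueError("temporal_penalty must be nonnegative")
        if self.n_options < 2:
            raise ValueError("need at least 2 scale options")


def build_design(
    experiment: int,
    n_subjects: int,
    rng_seed: int,
    conditions: tuple[str, ...] = ("original", "constant", "inverse", "variable"),
    E_values: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0),
    exp2_E: float = 30.0,
    n_blocks: int = 5,
) -> pd.DataFrame:
    """Blocked, within-block-randomized trial schedule.

    Experiment 1: each subject is assigned one timing condition
    (between-subjects, cycling through ``conditions``) and rates the six
    stiffness levels, five blocks of six trials (30 trials). Experiment 2:
    every subject rates the four timing conditions of the E = ``exp2_E`` path
    in five blocks of four (20 trials). Deterministic for a fixed seed.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng_seed)

    rows = []
    for subj in range(1, n_subjects + 1):
        if experiment == 1:
            cond = conditions[(subj - 1) % len(conditions)]
            stimuli = [(cond, E) for E in E_values]
        else:
            stimuli = [(c, exp2_E) for c in conditions]
        trial = 1
        for block in range(1, n_blocks + 1):
            order = rng.permutation(len(stimuli))
            for idx in order:
                cond, E = stimuli[idx]
                rows.append(
                    {
                        "subject_id": subj,
                        "experiment": experiment,
                        "condition": cond,
                        "E": E,
                        "block": block,
                        "trial_index": trial,
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


def quantize_rating(latent, n_options: int = 7):
    """Snap a latent rating on the [1, 7] continuum to the nearest scale level.

    The scale has ``n_options`` levels evenly spread over [1, 7]; with 7
    options the levels are the integers 1..7. Returns ``(level, value)``
    where ``level`` is the 1-based level index and ``value`` its position on
    the [1, 7] continuum. Fewer options mean coarser steps, hence larger
    quantization error.
    """
    latent = np.asarray(latent, dtype=float)
    step = (SCALE_HI - SCALE_LO) / (n_options - 1)
    level = np.clip(np.rint((latent - SCALE_LO) / step), 0, n_options - 1).astype(int)
    value = SCALE_LO + level * step
    return level + 1, value


def _feature_values(features: pd.DataFrame, name: str) -> pd.Series:
    sign = 1.0
    if name.startswith("-"):
        sign, name = -1.0, name[1:]
    if name not in features.columns:
        raise KeyError(f"unknown driving feature {name!r}")
    return sign * features[name]


def generate_ratings(
    schedule: pd.DataFrame,
    features: pd.DataFrame,
    subjects: SubjectModel | list[SubjectModel],
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate the rating of every scheduled trial.

    For each trial the latent rating is

        intercept + gain * z(feature) + temporal_penalty * [condition != original] + noise,

    where z standardizes the driving feature across the subject's own
    stimulus set (a set with no feature variation, as in Experiment 2,
    contributes z = 0), followed by shrinkage toward the scale midpoint and
    quantization. The returned frame adds ``rating`` (integer level) and
    ``rating_value`` (its position on the 1-7 continuum) columns.
    Reproducible bit-for-bit for a fixed ``rng_seed``.
    """
    subject_ids = sorted(schedule["subject_id"].unique())
    if isinstance(subjects, SubjectModel):
        subjects = [subjects] * len(subject_ids)
    if len(subjects) != len(subject_ids):
        raise ValueError("need one SubjectModel per subject")

    feat_key = features.set_index(["condition", "E"])
    out = schedule.copy().reset_index(drop=True)
    ratings = np.empty(len(out), dtype=int)
    values = np.empty(len(out), dtype=float)
    latents = np.empty(len(out), dtype=float)

    seeds = np.random.SeedSequence(rng_seed).spawn(len(subject_ids))
    for model, sid, seed in zip(subjects, subject_ids, seeds):
        rng = np.random.default_rng(seed)
        mask = (out["subject_id"] == sid).to_numpy()
        trials = out[mask]
        # standardize the driving feature over this subject's stimulus set
        stim_set = trials[["condition", "E"]].drop_duplicates()
        if model.driving_feature.lstrip("-") == "E":
            raw_set = stim_set["E"].astype(float)
            raw_set = raw_set if not model.driving_feature.startswith("-") else -raw_set
            raw_trials = trials["E"].astype(float)
            raw_trials = raw_trials if not model.driving_feature.startswith("-") else -raw_trials
        else:
            raw_set = stim_set.apply(
                lambda r: _feature_values(feat_key.loc[[(r["condition"], r["E"])]].reset_index(),
                                          model.driving_feature).iloc[0],
                axis=1,
            )
            raw_trials = trials.apply(
                lambda r: _feature_values(feat_key.loc[[(r["condition"], r["E"])]].reset_index(),
                                          model.driving_feature).iloc[0],
                axis=1,
            )
        mu, sd = float(np.mean(raw_set)), float(np.std(raw_set))
        z = (raw_trials.to_numpy() - mu) / sd if sd > 0 else np.zeros(mask.sum())

        latent = (
            model.intercept
            + model.gain * z
            + model.temporal_penalty * (trials["condition"] != "original").to_numpy()
            + rng.normal(0.0, model.noise_sd, size=mask.sum())
        )
        latent = SCALE_MID + (1.0 - model.central_tendency) * (latent - SCALE_MID)
        level, value = quantize_rating(latent, model.n_options)
        ratings[mask] = level
        values[mask] = value
        latents[mask] = latent

    out["rating"] = ratings
    out["rating_value"] = values
    out["latent"] = latents
    return out
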