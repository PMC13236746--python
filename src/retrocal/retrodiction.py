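"""Per-study retrodiction fits and effect-size conversions.

The retrodiction model regresses the condition-level standard scores on
the measured scores (``s ~ 1 + y``): a method retrodicts well when its
measured scores linearly recover the values the experimental
manipulation set.  Under repeated measures the predictor is centered on
each participant's mean, which matches (in residual sum of squares) a
fit with participant-level intercepts and removes stable between-person
offsets that are irrelevant to retrodiction.

Degrees of freedom follow the paired-design convention: for a balanced
two-condition study with one observation per subject and condition the
centered regression t-statistic equals the classical paired t with
``df = N - 1``, and the within-subject Cohen's d (d_z) satisfies
``t = d * sqrt(N)``.  For richer repeated-measures designs we use
``df = n_obs - n_subjects - 1`` (slope plus one intercept per subject).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .corpus import MethodId, StudyData
from .errors import AvailabilityError, DegenerateFitError, ValidationError

logger = logging.getLogger(__name__)

DfRule = Literal["auto", "paired", "per-observation"]


@dataclass(frozen=True)
class RetrodictionResult:
    """Retrodiction fit of one method in one study.

    Attributes
    ----------
    t_stat : float
        Signed t-statistic of the measured-score slope.
    df : int
        Degrees of freedom under the documented convention.
    pearson_r : float
        Retrodictive validity: correlation between standard scores and
        participant-mean-centered measured scores.
    cohen_d : float or None
        Within-subject standardized condition difference (d_z); only
        defined for two-condition designs.
    sd_within : float
        Pooled within-condition SD of the measured score, used as the
        calibration-side sigma_c in power analysis.
    n_subjects, n_obs : int
        Subjects contributing to the fit / rows used.
    n_pairs : int
        Subjects with both conditions (enter the d_z computation).
    """

    study_id: str
    method: MethodId
    t_stat: float
    df: int
    pearson_r: float
    cohen_d: Optional[float]
    sd_within: float
    n_subjects: int
    n_obs: int
    n_pairs: int


def t_from_d(cohen_d: float, n_subjects: int) -> float:
    """Paired-design t-statistic implied by a within-subject d_z:
    ``t = d * sqrt(N)``."""
    if n_subjects < 2:
        raise ValidationError("t_from_d requires n_subjects >= 2")
    return float(cohen_d) * math.sqrt(n_subjects)


def d_from_t(t_stat: float, n_subjects: int) -> float:
    """Inverse of :func:`t_from_d`."""
    if n_subjects < 2:
        raise ValidationError("d_from_t requires n_subjects >= 2")
    return float(t_stat) / math.sqrt(n_subjects)


def r_from_t(t_stat: float, df: int) -> float:
    """Pearson correlation implied by a t-statistic:
    ``r = t / sqrt(t^2 + df)``; strictly inside (-1, 1) for finite t."""
    if df < 1:
        raise ValidationError("r_from_t requires df >= 1")
    t = float(t_stat)
    return t / math.sqrt(t * t + df)


def t_from_r(pearson_r: float, df: int) -> float:
    """t-statistic of a correlation at the given df:
    ``t = r * sqrt(df) / sqrt(1 - r^2)``."""
    if df < 1:
        raise ValidationError("t_from_r requires df >= 1")
    r = float(pearson_r)
    if abs(r) >= 1.0:
        raise DegenerateFitError("|r| = 1: t-statistic is unbounded")
    return r * math.sqrt(df) / math.sqrt(1.0 - r * r)


def fit_retrodiction(
    study: StudyData,
    method: MethodId,
    df_rule: DfRule = "auto",
) -> RetrodictionResult:
    """Fit the retrodiction regression for one method in one study.

    The standard score is regressed on an intercept plus the
    participant-mean-centered measured score; the slope's t-statistic
    (under the df convention selected by ``df_rule``), the implied
    Pearson r, the two-condition Cohen's d_z where defined, and the
    pooled within-condition SD of the measured score are returned.

    ``df_rule``:

    * ``"auto"`` — paired convention (``N - 1``) for balanced
      two-condition, one-observation-per-cell data; otherwise
      per-observation (``n_obs - n_subjects - 1``);
    * ``"paired"`` / ``"per-observation"`` — force one convention.
    """
    if method not in study.methods_available:
        raise AvailabilityError(
            f"method {method!r} not measured in study {study.study_id}"
        )
    obs = study.observations(method)
    n_subjects = int(obs["subject"].nunique())
    if n_subjects < 3:
        raise DegenerateFitError(
            f"{study.study_id}/{method}: needs >= 3 subjects, got {n_subjects}"
        )

    s = obs["standard_score"].to_numpy(dtype=float)
    y = obs["measured_score"].to_numpy(dtype=float)
    subj_mean = obs.groupby("subject")["measured_score"].transform("mean")
    y_c = y - subj_mean.to_numpy(dtype=float)

    if np.ptp(y_c) == 0.0 or np.allclose(np.var(y_c), 0.0):
        raise DegenerateFitError(
            f"{study.study_id}/{method}: centered predictor has zero variance"
        )
    if np.ptp(s) == 0.0:
        raise DegenerateFitError(
            f"{study.study_id}/{method}: standard scores are constant"
        )

    r = float(np.corrcoef(s, y_c)[0, 1])

    conditions = sorted(obs["condition"].unique(), key=lambda c: str(c))
    n_cond = len(conditions)
    cell_counts = obs.groupby(["subject", "condition"]).size()
    one_per_cell = bool((cell_counts == 1).all())
    balanced = not (method in study.unbalanced_methods)
    is_paired_design = n_cond == 2 and one_per_cell and balanced

    if df_rule == "paired" or (df_rule == "auto" and is_paired_design):
        df = n_subjects - 1
    elif df_rule in ("per-observation", "auto"):
        df = len(obs) - n_subjects - 1
    else:
        raise ValidationError(f"unknown df_rule {df_rule!r}")
    if df < 1:
        raise DegenerateFitError(
            f"{study.study_id}/{method}: non-positive residual df ({df})"
        )
    t = t_from_r(r, df)

    # two-condition d_z from per-subject condition differences, oriented
    # so that a positive d means the measured score tracks the standard
    cohen_d = None
    n_pairs = 0
    if n_cond == 2:
        wide = obs.pivot_table(
            index="subject", columns="condition", values="measured_score", aggfunc="mean"
        )
        wide = wide.dropna()
        n_pairs = int(len(wide))
        if n_pairs < len(obs["subject"].unique()):
            logger.info(
                "%s/%s: %d subject(s) missing a condition dropped from d_z",
                study.study_id,
                method,
                obs["subject"].nunique() - n_pairs,
            )
        s_by_cond = obs.groupby("condition")["standard_score"].first()
        hi, lo = s_by_cond.sort_values(ascending=False).index[:2]
        if n_pairs >= 2:
            diffs = (wide[hi] - wide[lo]).to_numpy(dtype=float)
            sd_d = float(np.std(diffs, ddof=1))
            if sd_d > 0:
                cohen_d = float(np.mean(diffs)) / sd_d

    # pooled within-condition SD (Bessel-corrected per condition, pooled by df)
    ss = 0.0
    dof = 0
    for _, sub in obs.groupby("condition"):
        vals = sub["measured_score"].to_numpy(dtype=float)
        if len(vals) >= 2:
            ss += float(np.var(vals, ddof=1)) * (len(vals) - 1)
            dof += len(vals) - 1
    if dof == 0:
        raise DegenerateFitError(
            f"{study.study_id}/{method}: cannot pool within-condition SD"
        )
    sd_within = math.sqrt(ss / dof)

    return RetrodictionResult(
        study_id=study.study_id,
        method=str(method),
        t_stat=t,
        df=int(df),
        pearson_r=r,
        cohen_d=cohen_d,
        sd_within=sd_within,
        n_subjects=n_subjects,
        n_obs=int(len(obs)),
        n_pairs=n_pairs,
    )


def fit_all(study: StudyData, df_rule: DfRule = "auto") -> list[RetrodictionResult]:
    """Retrodiction fits for every method available in a study."""
    return [
        fit_retrodiction(study, m, df_rule=df_rule)
        for m in sorted(study.methods_available)
    ]
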