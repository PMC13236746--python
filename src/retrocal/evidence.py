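"""Meta-analytic evidence synthesis for calibration experiments.

Each study contributes a signed retrodiction t-statistic.  Under a
fixed-effect model (a common retrodictive effect across calibration
datasets) the statistics are combined by inverse-variance weighting,

    w_k = sqrt( v_k^{-1} / sum_j v_j^{-1} ),      T~ = sum_k w_k T_k,

with v_k the variance of study k's t-statistic (df_k / (df_k - 2) for a
central t).  The weights satisfy ``sum w_k^2 = 1``, so equal-evidence
studies combine Stouffer-style.  The combined statistic maps to a Bayes
factor for the retrodiction model against an intercept-only null (a
completely non-retrodictive, constant measurement) under a Gaussian
linear model with a g-prior on the coefficients:

    2 log BF10 = (N - 2) log(1 + g)
                 - (N - 1) log[ 1 + g (T~^2 / (N - 2) + 1)^{-1} ],

where N is the total sample size of the studies combined and g is the
g-prior scale, by default set to N.  Because every method is compared to
the same null, methods measured on partially non-overlapping study sets
remain jointly interpretable — subject to data homogeneity, which is why
the subject overlap between methods is reported alongside, and why a
comparison can be re-run restricted to fully overlapping studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .corpus import CalibrationCorpus, MethodId, StudyData, _SummaryGroup
from .errors import (
    AvailabilityError,
    EmptyCorpusError,
    UndefinedVarianceError,
    ValidationError,
)
from .retrodiction import DfRule, fit_retrodiction, r_from_t, t_from_d

logger = logging.getLogger(__name__)

GRule = Union[Literal["total-n"], float, int]


@dataclass(frozen=True)
class StudyWeight:
    """Inverse-variance weight of one study in a combination."""

    study_id: str
    t_variance: float
    weight: float


@dataclass(frozen=True)
class EvidenceResult:
    """Combined evidence for one method across the studies containing it."""

    method: MethodId
    studies_used: tuple[str, ...]
    combined_t: float
    total_n: int
    g_param: float
    log_bf10: float
    pooled_r: float
    studies_excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class RankEntry:
    """One row of a method ranking: evidence, gap to the best method, and
    the subject overlap with it (an index of comparison reliability)."""

    rank: int
    method: MethodId
    log_bf10: float
    delta_log_bf10: float
    overlap_with_best: Optional[int]


@dataclass
class OverlapMatrix:
    """Symmetric methods x methods matrix of summed subjects of studies
    containing both methods; the diagonal is each method's total N."""

    methods: list[MethodId]
    overlap_n: pd.DataFrame

    def __getitem__(self, pair: tuple[MethodId, MethodId]) -> int:
        m1, m2 = pair
        return int(self.overlap_n.loc[m1, m2])

    def to_frame(self) -> pd.DataFrame:
        return self.overlap_n.copy()


def variance_of_t(df: int) -> float:
    """Variance of a central t-distributed statistic: ``df / (df - 2)``.

    Undefined for df <= 2; such studies cannot enter a combination.
    """
    if df <= 2:
        raise UndefinedVarianceError(
            f"t-statistic variance undefined for df={df} (needs df >= 3)"
        )
    return df / (df - 2.0)


def combine_weights(
    variances: Sequence[float],
    study_ids: Sequence[str] | None = None,
) -> list[StudyWeight]:
    """Inverse-variance weights normalised so that ``sum w_k^2 = 1``."""
    if len(variances) == 0:
        raise ValidationError("combine_weights needs at least one variance")
    v = np.asarray(variances, dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValidationError("variances must be positive and finite")
    inv = 1.0 / v
    w = np.sqrt(inv / inv.sum())
    ids = list(study_ids) if study_ids is not None else [str(i) for i in range(len(v))]
    if len(ids) != len(v):
        raise ValidationError("study_ids and variances length mismatch")
    return [
        StudyWeight(study_id=i, t_variance=float(vk), weight=float(wk))
        for i, vk, wk in zip(ids, v, w)
    ]


def combine_t(
    t_stats: Sequence[float],
    weights: Sequence[StudyWeight],
) -> float:
    """Weighted combination ``T~ = sum w_k T_k`` of signed t-statistics.

    Effect directionality is carried by the sign of each T_k; a single
    study passes through unchanged.
    """
    if len(t_stats) != len(weights):
        raise ValidationError("t_stats and weights length mismatch")
    t = np.asarray(t_stats, dtype=float)
    w = np.asarray([sw.weight for sw in weights], dtype=float)
    return float(np.dot(w, t))


def log_bf10(combined_t: float, total_n: int, g_param: float | None = None) -> float:
    """Natural-log Bayes factor of the retrodiction model vs the
    intercept-only null, from the combined t-statistic under a g-prior.

    ``g_param`` defaults to ``total_n`` (unit-information prior).  The
    result is strictly increasing in ``combined_t**2`` and at t = 0
    collapses to ``-0.5 * log(1 + g)``.
    """
    n = int(total_n)
    if n <= 2:
        raise ValidationError(f"log_bf10 requires total_n >= 3, got {n}")
    g = float(g_param) if g_param is not None else float(n)
    if g <= 0:
        raise ValidationError("g_param must be positive")
    t2 = float(combined_t) ** 2
    two_log_bf = (n - 2) * math.log1p(g) - (n - 1) * math.log1p(g / (t2 / (n - 2) + 1.0))
    return 0.5 * two_log_bf


# ---------------------------------------------------------------------------
# corpus-level synthesis
# ---------------------------------------------------------------------------

def study_statistics(
    entry: Union[StudyData, _SummaryGroup],
    method: MethodId,
    df_rule: DfRule = "auto",
) -> tuple[float, int, int]:
    """(t, df, n_subjects) of one study for one method.

    Raw studies are fitted with :func:`fit_retrodiction`; summary-level
    studies convert the published within-subject d via ``t = d sqrt(N)``
    with ``df = N - 1`` (the paired convention).
    """
    if method not in entry.methods_available:
        raise AvailabilityError(
            f"method {method!r} not measured in study {entry.study_id}"
        )
    if isinstance(entry, StudyData):
        res = fit_retrodiction(entry, method, df_rule=df_rule)
        return res.t_stat, res.df, res.n_subjects
    n = entry.n_subjects(method)
    return t_from_d(entry.cohen_d(method), n), n - 1, n


def method_evidence(
    corpus: CalibrationCorpus,
    method: MethodId,
    g_rule: GRule = "total-n",
    df_rule: DfRule = "auto",
    variance_rule: Callable[[int], float] = variance_of_t,
) -> EvidenceResult:
    """Combine the evidence for one method over every study containing it.

    Studies whose df does not support a finite t-variance (df <= 2) are
    excluded with a logged warning rather than failing the synthesis.
    ``g_rule`` is either ``"total-n"`` (g equals the summed sample size
    of the studies used) or an explicit positive number.
    """
    used_ids: list[str] = []
    excluded: list[str] = []
    t_list: list[float] = []
    v_list: list[float] = []
    n_total = 0
    for entry in corpus.studies_with(method):
        t, df, n = study_statistics(entry, method, df_rule=df_rule)
        try:
            v = variance_rule(df)
        except UndefinedVarianceError:
            logger.warning(
                "study %s excluded for method %s: df=%d leaves the "
                "t-variance undefined",
                entry.study_id,
                method,
                df,
            )
            excluded.append(entry.study_id)
            continue
        used_ids.append(entry.study_id)
        t_list.append(t)
        v_list.append(v)
        n_total += n
    if not used_ids:
        raise AvailabilityError(
            f"method {method!r} has no eligible study (df >= 3) in the corpus"
        )
    weights = combine_weights(v_list, study_ids=used_ids)
    t_comb = combine_t(t_list, weights)
    g = float(n_total) if g_rule == "total-n" else float(g_rule)
    if g <= 0:
        raise ValidationError("g must be positive")
    lbf = log_bf10(t_comb, n_total, g)
    return EvidenceResult(
        method=str(method),
        studies_used=tuple(used_ids),
        combined_t=t_comb,
        total_n=n_total,
        g_param=g,
        log_bf10=lbf,
        pooled_r=r_from_t(t_comb, n_total - 2),
        studies_excluded=tuple(excluded),
    )


def all_method_evidence(
    corpus: CalibrationCorpus,
    g_rule: GRule = "total-n",
    df_rule: DfRule = "auto",
    variance_rule: Callable[[int], float] = variance_of_t,
) -> list[EvidenceResult]:
    """:func:`method_evidence` for every method present in the corpus."""
    return [
        method_evidence(corpus, m, g_rule=g_rule, df_rule=df_rule, variance_rule=variance_rule)
        for m in corpus.methods
    ]


def overlap_matrix(corpus: CalibrationCorpus) -> OverlapMatrix:
    """Summed subject overlap between every pair of methods.

    Entry (m1, m2) sums, over studies containing both methods, the
    smaller of the two per-method subject counts (they coincide in a
    complete within-study design).  The diagonal is each method's total
    N; the matrix is symmetric with off-diagonals bounded by the smaller
    diagonal.
    """
    if len(corpus) == 0:
        raise EmptyCorpusError("overlap_matrix needs a non-empty corpus")
    methods = corpus.methods
    mat = pd.DataFrame(0, index=methods, columns=methods, dtype=int)
    for entry in corpus:
        avail = sorted(entry.methods_available)
        for m1 in avail:
            for m2 in avail:
                mat.loc[m1, m2] += min(entry.n_subjects(m1), entry.n_subjects(m2))
    return OverlapMatrix(methods=methods, overlap_n=mat)


def restrict_to_overlap(
    corpus: CalibrationCorpus,
    methods: Sequence[MethodId],
) -> CalibrationCorpus:
    """Sub-corpus of studies containing *every* listed method — the most
    conservative footing for cross-method comparison."""
    wanted = set(methods)
    if not wanted:
        raise ValidationError("restrict_to_overlap needs at least one method")
    keep = [e.study_id for e in corpus if wanted <= set(e.methods_available)]
    if not keep:
        lines = [
            f"  {e.study_id}: {sorted(e.methods_available)}" for e in corpus
        ]
        raise EmptyCorpusError(
            "no study contains all of "
            + str(sorted(wanted))
            + "; per-study availability:\n"
            + "\n".join(lines)
        )
    return corpus.subset(keep)


def rank_methods(
    evidence: Sequence[EvidenceResult],
    overlap: OverlapMatrix | None = None,
) -> list[RankEntry]:
    """Rank methods by log Bayes factor (descending; ties broken by
    method name) and report each method's evidence gap to the best,
    annotated with its subject overlap with the best method."""
    if not evidence:
        raise ValidationError("rank_methods needs at least one result")
    ordered = sorted(evidence, key=lambda e: (-e.log_bf10, e.method))
    best = ordered[0]
    out = []
    for i, e in enumerate(ordered, start=1):
        ov = None
        if overlap is not None and e.method in overlap.methods and best.method in overlap.methods:
            ov = overlap[e.method, best.method]
        out.append(
            RankEntry(
                rank=i,
                method=e.method,
                log_bf10=e.log_bf10,
                delta_log_bf10=best.log_bf10 - e.log_bf10,
                overlap_with_best=ov,
            )
        )
    return out


def accumulate_evidence(
    corpus: CalibrationCorpus,
    method: MethodId,
    g_rule: GRule = "total-n",
    df_rule: DfRule = "auto",
) -> list[Optional[EvidenceResult]]:
    """Evidence trajectory over successive date-ordered corpus prefixes.

    One entry per prefix of the (date, study_id)-ordered study list.  At
    stages where the method has not yet appeared the entry is ``None``;
    at stages that add no study containing the method the previous
    result is carried forward unchanged.  The final entry equals
    :func:`method_evidence` on the full corpus.
    """
    out: list[Optional[EvidenceResult]] = []
    prev: Optional[EvidenceResult] = None
    for k in range(1, len(corpus) + 1):
        prefix = corpus.subset(corpus.study_ids[:k])
        has_method_now = any(method in e.methods_available for e in prefix)
        if not has_method_now:
            out.append(None)
            continue
        if prev is not None and method not in corpus.studies[k - 1].methods_available:
            out.append(prev)
            continue
        try:
            prev = method_evidence(prefix, method, g_rule=g_rule, df_rule=df_rule)
        except AvailabilityError:
            # the method is present but no study is yet eligible (df <= 2)
            out.append(prev)
            continue
        out.append(prev)
    return out
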