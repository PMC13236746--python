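"""Model/Results front end for calibration inference.

:class:`CalibrationModel` wraps a :class:`~retrocal.corpus.CalibrationCorpus`
together with the analysis conventions (df rule, t-variance rule, g
rule); ``fit()`` runs the per-study retrodiction fits and the
meta-analytic evidence synthesis for every method and returns a
:class:`CalibrationResults` carrying the evidence table, the subject
overlap matrix, the method ranking, and hooks for evidence-accumulation
trajectories, overlap-restricted refits, power/cost decisions, and
plotting.

Example
-------
>>> from retrocal import CalibrationModel, table1_fixture
>>> res = CalibrationModel(table1_fixture()).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .corpus import CalibrationCorpus, MethodId, StudyData, read_long_format, read_summary
from .decision import (
    DecisionReport,
    EffectSpec,
    PowerAlgorithm,
    PowerSpec,
    decision_report,
)
from .errors import ValidationError
from .evidence import (
    EvidenceResult,
    GRule,
    OverlapMatrix,
    RankEntry,
    accumulate_evidence,
    all_method_evidence,
    overlap_matrix,
    rank_methods,
    restrict_to_overlap,
    variance_of_t,
)
from .retrodiction import DfRule, RetrodictionResult, fit_all


class CalibrationModel:
    """Calibration inference model over a corpus of studies.

    Parameters
    ----------
    corpus : CalibrationCorpus
        Raw and/or summary-level calibration studies.
    df_rule : {"auto", "paired", "per-observation"}
        Degrees-of-freedom convention for raw-study retrodiction fits.
    g_rule : "total-n" or positive number
        g-prior scale; the default ties g to the combined sample size.
    variance_rule : callable
        Maps a study's df to the variance of its t-statistic (default:
        central-t, ``df / (df - 2)``).
    """

    def __init__(
        self,
        corpus: CalibrationCorpus,
        df_rule: DfRule = "auto",
        g_rule: GRule = "total-n",
        variance_rule: Callable[[int], float] = variance_of_t,
    ) -> None:
        if len(corpus) == 0:
            raise ValidationError("corpus is empty")
        self.corpus = corpus
        self.df_rule = df_rule
        self.g_rule = g_rule
        self.variance_rule = variance_rule

    # -- constructors -------------------------------------------------
    @classmethod
    def from_long_csv(cls, path, column_map=None, **kwargs) -> "CalibrationModel":
        """Build from a raw long-format CSV (see :func:`read_long_format`)."""
        return cls(read_long_format(path, column_map=column_map), **kwargs)

    @classmethod
    def from_summary_csv(cls, path, column_map=None, **kwargs) -> "CalibrationModel":
        """Build from a study-level summary CSV (see :func:`read_summary`)."""
        return cls(read_summary(path, column_map=column_map), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "CalibrationModel":
        """Build from an in-memory long-format DataFrame with columns
        ``study_id, date, subject, condition, standard_score, method,
        measured_score``."""
        studies = [
            StudyData(str(sid), str(sub["date"].iloc[0]), sub.drop(columns=["study_id", "date"]))
            for sid, sub in frame.groupby("study_id", sort=False)
        ]
        return cls(CalibrationCorpus(studies), **kwargs)

    # -- fitting ------------------------------------------------------
    def fit(self, restrict_to: Optional[Sequence[MethodId]] = None) -> "CalibrationResults":
        """Run retrodiction + evidence synthesis for every method.

        ``restrict_to`` limits the corpus to studies containing all the
        listed methods first (the overlap-restricted comparison).
        """
        corpus = (
            restrict_to_overlap(self.corpus, restrict_to) if restrict_to else self.corpus
        )
        retro: list[RetrodictionResult] = []
        for entry in corpus:
            if isinstance(entry, StudyData):
                retro.extend(fit_all(entry, df_rule=self.df_rule))
        evidence = all_method_evidence(
            corpus,
            g_rule=self.g_rule,
            df_rule=self.df_rule,
            variance_rule=self.variance_rule,
        )
        overlap = overlap_matrix(corpus)
        ranking = rank_methods(evidence, overlap=overlap)
        return CalibrationResults(self, corpus, retro, evidence, overlap, ranking)


class CalibrationResults:
    """Fitted calibration analysis.

    Attributes
    ----------
    retrodiction : list of RetrodictionResult
        Per-study, per-method fits (raw studies only).
    evidence : list of EvidenceResult
        Combined statistic, total N, g and log Bayes factor per method.
    overlap : OverlapMatrix
    ranking : list of RankEntry
    """

    def __init__(
        self,
        model: CalibrationModel,
        corpus: CalibrationCorpus,
        retrodiction: list[RetrodictionResult],
        evidence: list[EvidenceResult],
        overlap: OverlapMatrix,
        ranking: list[RankEntry],
    ) -> None:
        self.model = model
        self.corpus = corpus
        self.retrodiction = retrodiction
        self.evidence = evidence
        self.overlap = overlap
        self.ranking = ranking

    # -- tabular views ------------------------------------------------
    def evidence_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": e.method,
                "k_studies": len(e.studies_used),
                "total_n": e.total_n,
                "combined_t": e.combined_t,
                "pooled_r": e.pooled_r,
                "g": e.g_param,
                "log_bf10": e.log_bf10,
            }
            for e in self.evidence
        ]
        return pd.DataFrame(rows).set_index("method")

    def ranking_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": r.rank,
                "method": r.method,
                "log_bf10": r.log_bf10,
                "delta_log_bf10": r.delta_log_bf10,
                "overlap_with_best": r.overlap_with_best,
            }
            for r in self.ranking
        ]
        return pd.DataFrame(rows).set_index("rank")

    def retrodiction_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": r.study_id,
                "method": r.method,
                "t_stat": r.t_stat,
                "df": r.df,
                "pearson_r": r.pearson_r,
                "cohen_d": r.cohen_d,
                "sd_within": r.sd_within,
                "n_subjects": r.n_subjects,
            }
            for r in self.retrodiction
        ]
        return pd.DataFrame(rows)

    @property
    def best_method(self) -> MethodId:
        return self.ranking[0].method

    # -- downstream analyses ------------------------------------------
    def accumulate(self, method: MethodId) -> pd.DataFrame:
        """Date-ordered evidence-accumulation trajectory for one method."""
        traj = accumulate_evidence(
            self.corpus, method, g_rule=self.model.g_rule, df_rule=self.model.df_rule
        )
        rows = []
        for stage, (sid, e) in enumerate(zip(self.corpus.study_ids, traj), start=1):
            rows.append(
                {
                    "stage": stage,
                    "through_study": sid,
                    "method": method,
                    "k_studies": len(e.studies_used) if e else 0,
                    "total_n": e.total_n if e else 0,
                    "combined_t": e.combined_t if e else float("nan"),
                    "pooled_r": e.pooled_r if e else float("nan"),
                    "log_bf10": e.log_bf10 if e else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def refit_restricted(self, methods: Sequence[MethodId]) -> "CalibrationResults":
        """Overlap-restricted re-analysis over studies containing all
        the given methods."""
        return self.model.fit(restrict_to=methods)

    def decide(
        self,
        current: MethodId,
        candidate: MethodId,
        effect_spec: EffectSpec,
        power_spec: PowerSpec = PowerSpec(),
        cost_per_subject: float = 0.0,
        switch_cost: float = 0.0,
        groups: int = 2,
        currency: str = "EUR",
        algorithm: PowerAlgorithm = "approx",
    ) -> DecisionReport:
        """Evaluate the economics of switching ``current -> candidate``."""
        return decision_report(
            self.corpus,
            current,
            candidate,
            effect_spec,
            power_spec,
            cost_per_subject=cost_per_subject,
            switch_cost=switch_cost,
            groups=groups,
            currency=currency,
            algorithm=algorithm,
        )

    # -- presentation -------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        ev = self.evidence_frame()
        rk = self.ranking_frame()
        lines = [
            "Calibration evidence synthesis",
            "==============================",
            f"studies: {len(self.corpus)}   methods: {', '.join(self.corpus.methods)}",
            f"df rule: {self.model.df_rule}   g rule: {self.model.g_rule}",
            "",
            "Evidence (log Bayes factor vs intercept-only null)",
            ev.to_string(float_format=lambda x: f"{x:.3f}"),
            "",
            "Ranking (delta to best; overlap annotates comparability)",
            rk.to_string(float_format=lambda x: f"{x:.3f}"),
            "",
            "Subject overlap between methods",
            self.overlap.to_frame().to_string(),
        ]
        return "\n".join(lines)

    def plot_accumulation(self, methods: Optional[Sequence[MethodId]] = None, ax=None):
        """Evidence-accumulation trajectories (log BF vs integration
        stage), one line per method, line width scaled by total N."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for m in methods or self.corpus.methods:
            traj = self.accumulate(m)
            ax.plot(traj["stage"], traj["log_bf10"], marker="o", label=m)
        ax.set_xlabel("integration stage (date order)")
        ax.set_ylabel("log BF10 vs null")
        ax.legend(title="method")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CalibrationResults: {len(self.corpus)} studies, "
            f"best={self.best_method}>"
        )
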