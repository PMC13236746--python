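"""Synthetic calibration corpora with known ground truth.

The generator emulates the data-generating story of a two-condition
within-subject calibration experiment.  For subject j in condition c the
latent true score is

    tau_jc = s_c + aberration_jc,    aberration_jc ~ N(0, aberration_sd^2),

where s_c is the condition's standard score (default +1 / -1, the
CS+ / CS- analogue) and the aberration term captures an imperfect
experimental manipulation — true scores deviating from the standard
scores, which attenuates retrodictive validity for every method alike.
Each measurement method m then observes

    y_jcm = loading_m * tau_jc + b_jm + e_jcm,
    b_jm ~ N(0, subject_effect_sd^2),   e_jcm ~ N(0, noise_sd_m^2),

so methods differ in scale (loading), measurement error (noise_sd), and
per-study availability (a Bernoulli draw per study).  A method with
loading 0 carries no information about the latent variable — the null
measurement.

Randomness is split into independent streams keyed by (seed,
study_index, method), so adding a method to a config never perturbs the
draws of the others, and the same seed always reproduces the same
corpus.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .corpus import CalibrationCorpus, MethodId, StudyData
from .errors import ConfigError


@dataclass(frozen=True)
class MethodSpec:
    """Accuracy and availability of one simulated measurement method."""

    method: MethodId
    loading: float = 1.0
    noise_sd: float = 1.0
    availability_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.method:
            raise ConfigError("method label must be non-empty")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0.0 <= self.availability_prob <= 1.0:
            raise ConfigError("availability_prob must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Design of a simulated multi-study calibration corpus.

    ``subjects_per_study`` is either a fixed int or an inclusive
    (low, high) range sampled per study.  ``aberration_sd`` scales how
    far true scores stray from the standard scores (0 = a perfectly
    effective manipulation); ``subject_effect_sd`` adds stable
    between-person offsets that participant-mean centering removes.
    """

    n_studies: int = 5
    subjects_per_study: Union[int, tuple[int, int]] = (15, 30)
    standard_scores: tuple[float, float] = (1.0, -1.0)
    aberration_sd: float = 0.3
    subject_effect_sd: float = 0.5
    method_specs: Sequence[MethodSpec] = field(
        default_factory=lambda: (
            MethodSpec("A", loading=1.0, noise_sd=0.5),
            MethodSpec("B", loading=1.0, noise_sd=1.0),
        )
    )
    seed: int = 0
    start_date: str = "2020-01"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        if len(set(self.standard_scores)) < 2:
            raise ConfigError("need >= 2 distinct standard scores")
        if self.aberration_sd < 0 or self.subject_effect_sd < 0:
            raise ConfigError("SDs must be non-negative")
        if not self.method_specs:
            raise ConfigError("need at least one MethodSpec")
        names = [m.method for m in self.method_specs]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate method labels")
        n = self.subjects_per_study
        if isinstance(n, int):
            ok = n >= 3
        else:
            ok = len(n) == 2 and 3 <= n[0] <= n[1]
        if not ok:
            raise ConfigError("subjects_per_study must be >= 3 (or a valid range)")


def _stream(config_seed: int, study_index: int, *keys: str) -> np.random.Generator:
    """Independent RNG stream for (seed, study, key...)."""
    tokens = [int(config_seed) & 0x7FFFFFFF, int(study_index)]
    tokens += [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(tokens))


def _month_offset(start: str, k: int) -> str:
    year, month = int(start[:4]), int(start[5:7])
    total = year * 12 + (month - 1) + k
    return f"{total // 12:04d}-{total % 12 + 1:02d}"


def _n_subjects(config: GeneratorConfig, study_index: int) -> int:
    n = config.subjects_per_study
    if isinstance(n, int):
        return n
    rng = _stream(config.seed, study_index, "n_subjects")
    return int(rng.integers(n[0], n[1] + 1))


def _availability(config: GeneratorConfig, study_index: int) -> list[MethodSpec]:
    """Per-study method presence; resampled until >= 1 method present."""
    for attempt in range(1000):
        present = []
        for spec in config.method_specs:
            rng = _stream(config.seed, study_index, "avail", spec.method, str(attempt))
            if rng.random() < spec.availability_prob:
                present.append(spec)
        if present:
            return present
    # all probabilities zero (or absurdly small): fall back to everything
    return list(config.method_specs)


def generate_study(config: GeneratorConfig, study_index: int) -> StudyData:
    """One simulated study, deterministic given (config.seed, study_index)."""
    n_sub = _n_subjects(config, study_index)
    conditions = [f"c{i}" for i in range(len(config.standard_scores))]
    subjects = [f"s{j:03d}" for j in range(n_sub)]

    rng_tau = _stream(config.seed, study_index, "aberration")
    tau = np.empty((n_sub, len(conditions)))
    for ci, s_c in enumerate(config.standard_scores):
        tau[:, ci] = s_c + rng_tau.normal(0.0, config.aberration_sd, size=n_sub) \
            if config.aberration_sd > 0 else s_c

    present = _availability(config, study_index)
    frames = []
    for spec in present:
        rng_subj = _stream(config.seed, study_index, "subject_effect", spec.method)
        rng_noise = _stream(config.seed, study_index, "noise", spec.method)
        b = (
            rng_subj.normal(0.0, config.subject_effect_sd, size=n_sub)
            if config.subject_effect_sd > 0
            else np.zeros(n_sub)
        )
        for ci, cond in enumerate(conditions):
            y = spec.loading * tau[:, ci] + b + rng_noise.normal(
                0.0, spec.noise_sd, size=n_sub
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subject": subjects,
                        "condition": cond,
                        "standard_score": config.standard_scores[ci],
                        "method": spec.method,
                        "measured_score": y,
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    return StudyData(
        study_id=f"sim{study_index:03d}",
        date=_month_offset(config.start_date, study_index),
        data=data,
    )


def generate_corpus(config: GeneratorConfig) -> CalibrationCorpus:
    """A corpus of ``config.n_studies`` simulated studies with monthly
    acquisition dates."""
    studies = [generate_study(config, k) for k in range(config.n_studies)]
    return CalibrationCorpus(studies)
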