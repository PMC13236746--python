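"""From calibration results to sample sizes and money.

A substantive two-group experiment detects a standardized effect
``d = mu / sigma``, where ``mu`` is the between-group mean difference of
the measured score and ``sigma`` its pooled SD.  Calibration supplies
the method-specific ingredients:

* *direct* specification — a minimum effect magnitude ``mu_min`` on the
  measured-score scale is divided by the calibration within-group SD
  ``sigma_c``, deflated by an attenuation factor
  ``alpha = sigma_c / sigma`` in (0, 1] that encodes extra variability
  expected in the substantive experiment: ``d = alpha * mu_min / sigma_c``
  (alpha = 1 gives the upper bound ``mu_min / sigma_c``);
* *embedded* specification — when the substantive experiment embeds the
  calibration design (e.g. a placebo arm running the standard
  two-condition procedure), the minimum relevant between-group effect is
  anchored to the calibration effect size ``d_c``:  requiring the
  treatment-arm condition difference to exceed the placebo arm's by a
  fraction ``f`` gives ``d <= f * d_c`` (equality when sigma = sigma_c).

Required per-group sample sizes for a two-sample t-test then follow from
the usual normal-approximation formula (default) or an exact
noncentral-t computation, and the difference in total participants times
the per-subject cost, minus the one-off switch cost, is the net economic
benefit of adopting the more accurate method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Union

from scipy import stats

from .corpus import CalibrationCorpus, MethodId
from .errors import AvailabilityError, ConfigError, ValidationError

Tails = Literal["one", "two"]
PowerAlgorithm = Literal["approx", "exact"]


@dataclass(frozen=True)
class PowerSpec:
    """Error rates and design of the substantive experiment."""

    alpha_level: float = 0.05
    power: float = 0.8
    tails: Tails = "one"
    design: Literal["two_sample"] = "two_sample"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_level < 1.0:
            raise ConfigError("alpha_level must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ConfigError("power must be in (0, 1)")
        if self.power <= self.alpha_level:
            raise ConfigError("power must exceed alpha_level")
        if self.tails not in ("one", "two"):
            raise ConfigError("tails must be 'one' or 'two'")


#: scalar applying to every method, or a per-method mapping
PerMethod = Union[float, Mapping[MethodId, float]]


def _resolve(value: PerMethod, method: MethodId, what: str) -> float:
    if isinstance(value, Mapping):
        if method not in value:
            raise ConfigError(f"no {what} given for method {method!r}")
        return float(value[method])
    return float(value)


@dataclass(frozen=True)
class DirectEffectSpec:
    """Minimum effect magnitude on the measured-score scale, converted
    to Cohen's d via the calibration within-group SD."""

    mu_min: float
    sigma_c: PerMethod
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.attenuation <= 1.0:
            raise ConfigError("attenuation must be in (0, 1]")


@dataclass(frozen=True)
class EmbeddedEffectSpec:
    """Minimum relevant effect anchored to the calibration effect size
    d_c of each method (embedded-calibration design)."""

    d_c: PerMethod
    relative_fraction: float = 0.5
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_fraction <= 0:
            raise ConfigError("relative_fraction must be positive")
        if not 0.0 < self.attenuation <= 1.0:
            raise ConfigError("attenuation must be in (0, 1]")


EffectSpec = Union[DirectEffectSpec, EmbeddedEffectSpec]


@dataclass(frozen=True)
class DecisionReport:
    """Outcome of a method-switch evaluation."""

    method_current: MethodId
    method_candidate: MethodId
    d_current: float
    d_candidate: float
    n_current: int
    n_candidate: int
    groups: int
    participants_saved: int
    cost_per_subject: float
    switch_cost: float
    net_benefit: float
    currency: str = "EUR"

    def narrative(self) -> str:
        """Plain-language account of the switch evaluation."""
        lines = [
            f"Switching from {self.method_current} to {self.method_candidate}:",
            f"  minimum relevant effect size: d = {self.d_current:.2f} "
            f"({self.method_current}) vs d = {self.d_candidate:.2f} "
            f"({self.method_candidate})",
            f"  required sample size per group: {self.n_current} vs "
            f"{self.n_candidate}",
            f"  participants saved over {self.groups} groups: "
            f"{self.participants_saved}",
            f"  at {self.cost_per_subject:g} {self.currency}/participant, "
            f"minus a switch cost of {self.switch_cost:g} {self.currency}: "
            f"net benefit {self.net_benefit:g} {self.currency}",
        ]
        return "\n".join(lines)


def effect_size_direct(spec: DirectEffectSpec, method: MethodId | None = None) -> float:
    """``d = attenuation * mu_min / sigma_c`` (attenuation = 1 gives the
    upper bound ``mu_min / sigma_c``)."""
    sigma_c = (
        _resolve(spec.sigma_c, method, "sigma_c") if method is not None else float(spec.sigma_c)
    )
    if sigma_c <= 0:
        raise ValidationError("sigma_c must be positive")
    return spec.attenuation * spec.mu_min / sigma_c


def effect_size_embedded(spec: EmbeddedEffectSpec, method: MethodId | None = None) -> float:
    """``d = attenuation * relative_fraction * d_c``."""
    d_c = _resolve(spec.d_c, method, "d_c") if method is not None else float(spec.d_c)
    return spec.attenuation * spec.relative_fraction * d_c


def required_n(
    d: float,
    spec: PowerSpec = PowerSpec(),
    algorithm: PowerAlgorithm = "approx",
) -> int:
    """Per-group sample size of a two-sample t-test detecting effect d.

    ``"approx"`` (default) uses the normal-approximation formula
    ``n = ceil( 2 (z_{1-alpha*} + z_{power})^2 / d^2 )`` with
    ``alpha* = alpha`` one-tailed and ``alpha/2`` two-tailed.
    ``"exact"`` solves the noncentral-t power equation via statsmodels;
    it is typically one subject more conservative.
    """
    if d <= 0:
        raise ValidationError("required_n needs d > 0")
    alpha_star = spec.alpha_level if spec.tails == "one" else spec.alpha_level / 2.0
    if algorithm == "approx":
        z_a = stats.norm.ppf(1.0 - alpha_star)
        z_b = stats.norm.ppf(spec.power)
        return math.ceil(2.0 * (z_a + z_b) ** 2 / (d * d))
    if algorithm == "exact":
        from statsmodels.stats.power import TTestIndPower

        alternative = "larger" if spec.tails == "one" else "two-sided"
        n = TTestIndPower().solve_power(
            effect_size=d,
            alpha=spec.alpha_level,
            power=spec.power,
            alternative=alternative,
        )
        return math.ceil(n)
    raise ConfigError(f"unknown power algorithm {algorithm!r}")


def economic_benefit(
    n_current: int,
    n_candidate: int,
    groups: int = 2,
    cost_per_subject: float = 0.0,
    switch_cost: float = 0.0,
) -> tuple[int, float]:
    """(participants_saved, net_benefit) of moving from a method needing
    ``n_current`` per group to one needing ``n_candidate``.

    Savings are ``groups * (n_current - n_candidate)`` participants; the
    net benefit multiplies by the per-subject cost and subtracts the
    one-off switch cost.  Both may be negative (the switch loses money).
    """
    if min(n_current, n_candidate, groups) <= 0:
        raise ValidationError("sample sizes and groups must be positive")
    if cost_per_subject < 0 or switch_cost < 0:
        raise ValidationError("costs must be non-negative")
    saved = groups * (int(n_current) - int(n_candidate))
    return saved, saved * float(cost_per_subject) - float(switch_cost)


def decision_report(
    corpus: Optional[CalibrationCorpus],
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
    """End-to-end switch evaluation between two methods.

    Per-method minimum effect sizes come from ``effect_spec`` (for
    embedded specs, each method's own calibration d_c); required
    per-group n from :func:`required_n`; the monetary bottom line from
    :func:`economic_benefit`.  When a corpus is supplied, both methods
    must be present in it.
    """
    if corpus is not None:
        present = set(corpus.methods)
        for m in (current, candidate):
            if m not in present:
                raise AvailabilityError(f"method {m!r} has no data in the corpus")
    if isinstance(effect_spec, DirectEffectSpec):
        d_cur = effect_size_direct(effect_spec, current)
        d_cand = effect_size_direct(effect_spec, candidate)
    elif isinstance(effect_spec, EmbeddedEffectSpec):
        d_cur = effect_size_embedded(effect_spec, current)
        d_cand = effect_size_embedded(effect_spec, candidate)
    else:
        raise ConfigError(f"unsupported effect spec {type(effect_spec).__name__}")
    n_cur = required_n(d_cur, power_spec, algorithm=algorithm)
    n_cand = required_n(d_cand, power_spec, algorithm=algorithm)
    saved, net = economic_benefit(
        n_cur, n_cand, groups=groups, cost_per_subject=cost_per_subject, switch_cost=switch_cost
    )
    return DecisionReport(
        method_current=str(current),
        method_candidate=str(candidate),
        d_current=d_cur,
        d_candidate=d_cand,
        n_current=n_cur,
        n_candidate=n_cand,
        groups=int(groups),
        participants_saved=saved,
        cost_per_subject=float(cost_per_subject),
        switch_cost=float(switch_cost),
        net_benefit=net,
        currency=currency,
    )
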