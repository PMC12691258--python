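"""Single-test Bayesian machinery.

Everything in this module works on *expected* (deductive) headcounts: a
cohort of known size and prevalence is split by one imperfect test into a
positive and a negative subcohort, each with an exactly-deduced updated
prevalence.  Counts are real-valued throughout; there is no stochastic
rounding inside a computation, and prevalences are plain probabilities in
[0, 1] at full double precision (percent / per-100,000 are I/O conveniences
handled elsewhere).

Undefined quantities (likelihood ratios of a perfect test, the prevalence
of an empty branch) are represented as ``None`` — never as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import UndefinedQuantityError, ValidationError

__all__ = [
    "TestCharacteristics",
    "CohortState",
    "SplitResult",
    "derive_rates",
    "bayes_split",
    "posterior_after_profile",
]


def _check_probability(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:  # non-numeric input
        raise ValidationError(f"{name} must be a number, got {value!r}") from exc
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity of one test round plus derived quantities.

    Attributes
    ----------
    sensitivity : float
        P(test positive | sick).
    specificity : float
        P(test negative | healthy).
    p_false_positive : float
        1 - specificity.
    p_false_negative : float
        1 - sensitivity.
    lr_positive : float or None
        sensitivity / (1 - specificity); ``None`` when specificity == 1.
    lr_negative : float or None
        (1 - sensitivity) / specificity; ``None`` when specificity == 0.
    """

    sensitivity: float
    specificity: float
    p_false_positive: float = field(init=False)
    p_false_negative: float = field(init=False)
    lr_positive: Optional[float] = field(init=False)
    lr_negative: Optional[float] = field(init=False)

    def __post_init__(self) -> None:
        sens = _check_probability("sensitivity", self.sensitivity)
        spec = _check_probability("specificity", self.specificity)
        object.__setattr__(self, "sensitivity", sens)
        object.__setattr__(self, "specificity", spec)
        object.__setattr__(self, "p_false_positive", 1.0 - spec)
        object.__setattr__(self, "p_false_negative", 1.0 - sens)
        lr_pos = sens / (1.0 - spec) if spec < 1.0 else None
        lr_neg = (1.0 - sens) / spec if spec > 0.0 else None
        object.__setattr__(self, "lr_positive", lr_pos)
        object.__setattr__(self, "lr_negative", lr_neg)


def derive_rates(sensitivity: float, specificity: float) -> TestCharacteristics:
    """Build :class:`TestCharacteristics` from sensitivity and specificity.

    Likelihood ratios with a zero denominator are flagged as ``None``
    rather than fabricated.

    Raises
    ------
    ValidationError
        If either argument falls outside [0, 1].
    """
    return TestCharacteristics(sensitivity=sensitivity, specificity=specificity)


@dataclass(frozen=True)
class CohortState:
    """An (expected size, prevalence, test-history label) triple.

    ``size`` is an expected headcount and may be fractional.  The
    ``profile_label`` is a string over {'+', '-'} recording the outcome of
    every test applied so far (empty at the root).
    """

    size: float
    prevalence: float
    profile_label: str = ""

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValidationError(f"size must be >= 0, got {self.size!r}")
        _check_probability("prevalence", self.prevalence)
        if set(self.profile_label) - {"+", "-"}:
            raise ValidationError(
                f"profile_label must use only '+'/'-', got {self.profile_label!r}"
            )


@dataclass(frozen=True)
class SplitResult:
    """All ten expected-count / prevalence quantities of one Bayesian split.

    ``prevalence_pos`` / ``prevalence_neg`` are ``None`` when the
    corresponding branch is empty (zero expected headcount).
    """

    n_sick: float
    n_healthy: float
    n_tp: float
    n_fp: float
    n_tn: float
    n_fn: float
    n_pos: float
    n_neg: float
    prevalence_pos: Optional[float]
    prevalence_neg: Optional[float]


def bayes_split(cohort: CohortState, test: TestCharacteristics) -> SplitResult:
    """Split a cohort by one test outcome and deduce subcohort prevalences.

    The computation follows the expected-count chain

        n_sick    = size * prevalence
        n_healthy = size - n_sick
        n_fn      = n_sick * (1 - sensitivity)
        n_fp      = n_healthy * (1 - specificity)
        n_tp      = n_sick - n_fn
        n_tn      = n_healthy - n_fp
        n_pos     = n_tp + n_fp
        n_neg     = n_tn + n_fn
        prevalence_pos = n_tp / n_pos
        prevalence_neg = n_fn / n_neg

    with the two posteriors reported as ``None`` for an empty branch.
    A zero-size cohort returns an all-zero result.
    """
    n_sick = cohort.size * cohort.prevalence
    n_healthy = cohort.size - n_sick
    n_fn = n_sick * test.p_false_negative
    n_fp = n_healthy * test.p_false_positive
    n_tp = n_sick - n_fn
    n_tn = n_healthy - n_fp
    n_pos = n_tp + n_fp
    n_neg = n_tn + n_fn
    prevalence_pos = n_tp / n_pos if n_pos > 0 else None
    prevalence_neg = n_fn / n_neg if n_neg > 0 else None
    return SplitResult(
        n_sick=n_sick,
        n_healthy=n_healthy,
        n_tp=n_tp,
        n_fp=n_fp,
        n_tn=n_tn,
        n_fn=n_fn,
        n_pos=n_pos,
        n_neg=n_neg,
        prevalence_pos=prevalence_pos,
        prevalence_neg=prevalence_neg,
    )


def posterior_after_profile(
    prior: float,
    test: TestCharacteristics,
    k_pos: int,
    k_neg: int,
) -> float:
    """Closed-form posterior P(sick) after ``k_pos`` positive and ``k_neg``
    negative results of the same test.

    Equivalent to applying :func:`bayes_split` ``k_pos + k_neg`` times in any
    order and reading off the prevalence of the corresponding branch:

        posterior odds = prior odds * lr_positive**k_pos * lr_negative**k_neg

    Raises
    ------
    ValidationError
        If ``prior`` is out of range or an exponent is negative.
    UndefinedQuantityError
        If a likelihood ratio needed with a nonzero exponent is undefined.
    """
    prior = _check_probability("prior", prior)
    for name, k in (("k_pos", k_pos), ("k_neg", k_neg)):
        if int(k) != k or k < 0:
            raise ValidationError(f"{name} must be a nonnegative integer, got {k!r}")
    k_pos, k_neg = int(k_pos), int(k_neg)
    if k_pos > 0 and test.lr_positive is None:
        raise UndefinedQuantityError(
            "lr_positive is undefined (specificity == 1); cannot apply a positive result"
        )
    if k_neg > 0 and test.lr_negative is None:
        raise UndefinedQuantityError(
            "lr_negative is undefined (specificity == 0); cannot apply a negative result"
        )
    if prior == 0.0:
        return 0.0
    if prior == 1.0:
        return 1.0
    if k_pos == 0 and k_neg == 0:
        return prior
    odds = prior / (1.0 - prior)
    if k_pos:
        odds *= test.lr_positive**k_pos
    if k_neg:
        odds *= test.lr_negative**k_neg
    if odds == float("inf"):
        return 1.0
    return odds / (1.0 + odds)
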