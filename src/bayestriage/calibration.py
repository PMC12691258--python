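"""Deduce priors (prevalence, sensitivity, specificity) from observed data.

Two sources are supported:

* a confusion table of integer TP/FP/TN/FN counts from a validated study;
* a stratified-prevalence indicator (e.g. an age band), for which *two*
  distinct rate conventions exist and are returned side by side, explicitly
  labelled, because conflating them is an easy and consequential mistake:

  - the predictive-value complements: healthy fraction *among*
    indicator-positives (1 - PPV) and sick fraction *among*
    indicator-negatives (1 - NPV);
  - the test-characteristic rates: P(indicator+ | healthy) = 1 - specificity
    and P(indicator- | sick) = 1 - sensitivity.

All arithmetic is exact (:class:`fractions.Fraction`) before any display
rounding; undefined quantities (zero denominators) come back as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .core_bayes import TestCharacteristics, derive_rates
from .errors import ValidationError

__all__ = [
    "ConfusionTable",
    "CalibrationResult",
    "StratumSpec",
    "IndicatorRates",
    "from_confusion",
    "indicator_rates",
]


def _check_count(name: str, value: int) -> int:
    if int(value) != value or value < 0:
        raise ValidationError(f"{name} must be a nonnegative integer, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class ConfusionTable:
    """Integer TP/FP/TN/FN counts from a gold-standard validation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.tp + self.fn < 1:
            raise ValidationError("tp + fn must be >= 1 to define sensitivity")
        if self.fp + self.tn < 1:
            raise ValidationError("fp + tn must be >= 1 to define specificity")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CalibrationResult:
    """Exact rational rates deduced from a confusion table.

    ``test`` carries the same sensitivity/specificity as floats for use by
    the splitting machinery; the Fraction fields are the source of truth.
    """

    prevalence: Fraction
    sensitivity: Fraction
    specificity: Fraction
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    lr_positive: Optional[Fraction]
    lr_negative: Optional[Fraction]
    test: TestCharacteristics


def from_confusion(table: ConfusionTable) -> CalibrationResult:
    """Deduce prevalence, sensitivity, specificity, PPV, NPV and LR+/- .

    prevalence = (tp + fn) / total, sensitivity = tp / (tp + fn),
    specificity = tn / (fp + tn), ppv = tp / (tp + fp),
    npv = tn / (tn + fn); quantities with a zero denominator are ``None``.
    """
    sensitivity = Fraction(table.tp, table.tp + table.fn)
    specificity = Fraction(table.tn, table.fp + table.tn)
    prevalence = Fraction(table.tp + table.fn, table.total)
    ppv = Fraction(table.tp, table.tp + table.fp) if table.tp + table.fp else None
    npv = Fraction(table.tn, table.tn + table.fn) if table.tn + table.fn else None
    lr_positive = sensitivity / (1 - specificity) if specificity != 1 else None
    lr_negative = (1 - sensitivity) / specificity if specificity != 0 else None
    return CalibrationResult(
        prevalence=prevalence,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        lr_positive=lr_positive,
        lr_negative=lr_negative,
        test=derive_rates(float(sensitivity), float(specificity)),
    )


@dataclass(frozen=True)
class StratumSpec:
    """A stratum (e.g. an age band) inside a cohort with known sick counts."""

    cohort_size: int
    cohort_sick: int
    stratum_size: int
    stratum_sick: int

    def __post_init__(self) -> None:
        for name in ("cohort_size", "cohort_sick", "stratum_size", "stratum_sick"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.cohort_sick > self.cohort_size:
            raise ValidationError("cohort_sick must not exceed cohort_size")
        if self.stratum_size > self.cohort_size:
            raise ValidationError("stratum_size must not exceed cohort_size")
        if self.stratum_sick > self.stratum_size:
            raise ValidationError("stratum_sick must not exceed stratum_size")
        if self.stratum_sick > self.cohort_sick:
            raise ValidationError("stratum_sick must not exceed cohort_sick")


@dataclass(frozen=True)
class IndicatorRates:
    """Both rate conventions for a stratum indicator, explicitly labelled.

    ``complement_ppv`` / ``complement_npv`` follow the predictive-value
    reading (healthy among in-stratum; sick among out-of-stratum), while
    ``one_minus_specificity`` / ``one_minus_sensitivity`` are the standard
    test-characteristic rates.  Do not feed the former into a split as if
    they were the latter.
    """

    stratum_prevalence: Optional[Fraction]
    complement_ppv: Optional[Fraction]
    complement_npv: Optional[Fraction]
    one_minus_specificity: Optional[Fraction]
    one_minus_sensitivity: Optional[Fraction]


def indicator_rates(stratum: StratumSpec) -> IndicatorRates:
    """Deduce both rate conventions for treating stratum membership as a test.

    With N the cohort, S its sick count, n the stratum and s its sick count:

    * stratum_prevalence     = s / n
    * complement_ppv         = (n - s) / n         (healthy among in-stratum)
    * complement_npv         = (S - s) / (N - n)   (sick among out-of-stratum)
    * one_minus_specificity  = (n - s) / (N - S)   (healthy captured by stratum)
    * one_minus_sensitivity  = (S - s) / S         (sick missed by stratum)

    Zero denominators yield ``None`` for the affected field only.
    """
    N, S = stratum.cohort_size, stratum.cohort_sick
    n, s = stratum.stratum_size, stratum.stratum_sick
    return IndicatorRates(
        stratum_prevalence=Fraction(s, n) if n else None,
        complement_ppv=Fraction(n - s, n) if n else None,
        complement_npv=Fraction(S - s, N - n) if N - n else None,
        one_minus_specificity=Fraction(n - s, N - S) if N - S else None,
        one_minus_sensitivity=Fraction(S - s, S) if S else None,
    )
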