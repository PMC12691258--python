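"""Action tiers and headline triage metrics.

Aggregated profile rows are mapped to one of three tiers:

* ``urgent``  — posterior at or above an absolute threshold; send straight
  to the confirmatory procedure.
* ``retest``  — posterior at least ``elevated_multiplier`` times a reference
  prevalence; offer further cheap tests.
* ``defer``   — everything else.

Headline integer headcounts are reported under two integerisation policies
because source tables are themselves inconsistent about rounding:
``floor`` (canonical: floor of the summed fractional urgent count) and
``nearest`` (half-up of the same sum).  Per-row floors are also exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .cohort_tree import AggregatedRow
from .errors import ValidationError
from ._rounding import round_half_up

__all__ = ["Tier", "TierSpec", "TierReport", "assign_tiers", "waiting_list_reduction"]

URGENT = "urgent"
RETEST = "retest"
DEFER = "defer"
Tier = str


@dataclass(frozen=True)
class TierSpec:
    """Thresholds driving tier assignment."""

    urgent_threshold: float = 0.04
    elevated_multiplier: float = 10.0
    reference_prevalence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.urgent_threshold <= 1.0:
            raise ValidationError(
                f"urgent_threshold must lie in (0, 1], got {self.urgent_threshold!r}"
            )
        if self.elevated_multiplier <= 1.0:
            raise ValidationError(
                f"elevated_multiplier must exceed 1, got {self.elevated_multiplier!r}"
            )
        if not 0.0 <= self.reference_prevalence <= 1.0:
            raise ValidationError(
                f"reference_prevalence must lie in [0, 1], "
                f"got {self.reference_prevalence!r}"
            )


@dataclass(frozen=True)
class TierReport:
    """Per-profile tier assignment plus headline urgent counts.

    ``urgent_count_integer`` floors the summed fractional urgent headcount
    (canonical policy); ``urgent_count_nearest`` rounds it half-up.
    ``reduction_percent`` uses the canonical integer.
    """

    tiers: Dict[str, Tier]
    cohort_size: float
    urgent_count_fractional: float
    urgent_count_integer: int
    urgent_count_nearest: int
    urgent_row_floors: Dict[str, int] = field(default_factory=dict)

    @property
    def reduction_percent(self) -> float:
        return 100.0 * (self.cohort_size - self.urgent_count_integer) / self.cohort_size

    @property
    def reduction_percent_nearest(self) -> float:
        return 100.0 * (self.cohort_size - self.urgent_count_nearest) / self.cohort_size


def assign_tiers(rows: Sequence[AggregatedRow], spec: TierSpec) -> TierReport:
    """Assign every profile of one aggregation depth to exactly one tier.

    The urgent tier contains all profiles whose posterior is at or above
    ``spec.urgent_threshold``.  Empty profiles (no expected headcount) are
    deferred.

    Raises
    ------
    ValidationError
        If ``rows`` is empty.
    """
    if not rows:
        raise ValidationError("rows must be a nonempty list of AggregatedRow")
    tiers: Dict[str, Tier] = {}
    urgent_fractional = 0.0
    urgent_row_floors: Dict[str, int] = {}
    cohort_size = 0.0
    retest_floor = spec.elevated_multiplier * spec.reference_prevalence
    for row in rows:
        cohort_size += row.concerned
        posterior = row.posterior
        if posterior is None:
            tier = DEFER
        elif posterior >= spec.urgent_threshold:
            tier = URGENT
        elif retest_floor > 0.0 and posterior >= retest_floor:
            tier = RETEST
        else:
            tier = DEFER
        tiers[row.profile.label] = tier
        if tier == URGENT:
            urgent_fractional += row.concerned
            urgent_row_floors[row.profile.label] = math.floor(row.concerned)
    return TierReport(
        tiers=tiers,
        cohort_size=cohort_size,
        urgent_count_fractional=urgent_fractional,
        urgent_count_integer=math.floor(urgent_fractional),
        urgent_count_nearest=int(round_half_up(urgent_fractional, 0)),
        urgent_row_floors=urgent_row_floors,
    )


def waiting_list_reduction(report: TierReport, cohort_size: float) -> float:
    """Percent of the cohort spared an urgent confirmatory procedure.

    ``100 * (cohort_size - urgent_count_integer) / cohort_size``, returned
    at full precision (display rounds to one decimal).
    """
    if cohort_size <= 0:
        raise ValidationError(f"cohort_size must be > 0, got {cohort_size!r}")
    return 100.0 * (cohort_size - report.urgent_count_integer) / cohort_size
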