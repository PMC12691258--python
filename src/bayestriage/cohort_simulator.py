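"""Patient-level Monte-Carlo oracle for the analytic expectations.

Disease status is Bernoulli(prevalence) per patient; test rounds are
conditionally independent given status (positive with probability
``sensitivity`` for the sick, ``1 - specificity`` for the healthy).  Only
the number of positive rounds matters downstream, so per-patient outcomes
are drawn as binomial counts.

Draw order is fixed for platform-stable reproducibility: one
``numpy.random.default_rng(seed)`` generator produces (1) the status vector,
(2) positive-round counts for all sick patients in cohort order, then
(3) counts for all healthy patients in cohort order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_tree import CohortState, aggregate_profiles, profile_label
from .core_bayes import TestCharacteristics
from .errors import ValidationError

__all__ = ["SimulationConfig", "SimulationResult", "simulate"]


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    prevalence: float
    test: TestCharacteristics
    n_rounds: int
    seed: int

    def __post_init__(self) -> None:
        if int(self.n_patients) != self.n_patients or self.n_patients < 1:
            raise ValidationError(
                f"n_patients must be a positive integer, got {self.n_patients!r}"
            )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(
                f"prevalence must lie in [0, 1], got {self.prevalence!r}"
            )
        if int(self.n_rounds) != self.n_rounds or self.n_rounds < 1:
            raise ValidationError(
                f"n_rounds must be a positive integer, got {self.n_rounds!r}"
            )


@dataclass(frozen=True)
class SimulationResult:
    """Observed vs expected per-profile counts.

    ``table`` has one row per (k positives of n_rounds) profile with columns
    ``n_positive``, ``label``, ``observed_sick``, ``observed_healthy``,
    ``observed``, ``expected_sick``, ``expected_healthy``, ``expected`` and
    ``z`` (deviation of ``observed`` in binomial standard deviations).
    """

    config: SimulationConfig
    n_sick_realised: int
    table: pd.DataFrame


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run one seeded cohort simulation and compare to analytic expectations."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sick = rng.random(n) < config.prevalence
    n_sick = int(sick.sum())
    positives = np.zeros(n, dtype=np.int64)
    positives[sick] = rng.binomial(config.n_rounds, config.test.sensitivity, n_sick)
    positives[~sick] = rng.binomial(
        config.n_rounds, config.test.p_false_positive, n - n_sick
    )

    k_values = np.arange(config.n_rounds + 1)
    observed_sick = np.bincount(positives[sick], minlength=config.n_rounds + 1)
    observed_healthy = np.bincount(positives[~sick], minlength=config.n_rounds + 1)

    rows = aggregate_profiles(
        CohortState(float(n), config.prevalence), config.test, config.n_rounds
    )
    expected_sick = np.zeros(config.n_rounds + 1)
    expected_healthy = np.zeros(config.n_rounds + 1)
    for row in rows:
        expected_sick[row.profile.n_positive] = row.sick
        expected_healthy[row.profile.n_positive] = row.healthy

    expected = expected_sick + expected_healthy
    observed = observed_sick + observed_healthy
    p_profile = expected / n
    sigma = np.sqrt(n * p_profile * (1.0 - p_profile))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (observed - expected) / sigma, 0.0)

    table = pd.DataFrame(
        {
            "n_positive": k_values,
            "label": [
                profile_label(int(k), config.n_rounds - int(k)) for k in k_values
            ],
            "observed_sick": observed_sick,
            "observed_healthy": observed_healthy,
            "observed": observed,
            "expected_sick": expected_sick,
            "expected_healthy": expected_healthy,
            "expected": expected,
            "z": z,
        }
    )
    assert int(table["observed"].sum()) == n
    assert int(table["observed_sick"].sum()) == n_sick
    return SimulationResult(config=config, n_sick_realised=n_sick, table=table)
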