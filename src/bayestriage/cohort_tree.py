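"""Recursive cohort expansion and order-invariant profile aggregation.

A depth-``d`` expansion applies one Bayesian split per level, yielding a
full binary tree whose 2**d leaves are the per-ordering subcohorts.  Because
the posterior only depends on *how many* tests were positive (not on their
order), leaves are aggregated into d+1 outcome profiles with binomial
multiplicities; the aggregation is cross-checked against the closed form

    sick(k)    = n_sick_root    * C(d, k) * sens**k * (1 - sens)**(d - k)
    healthy(k) = n_healthy_root * C(d, k) * (1 - spec)**k * spec**(d - k)

and an :class:`~bayestriage.errors.InternalInconsistencyError` is raised if
the two routes disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Optional, Tuple

import pandas as pd

from .core_bayes import CohortState, SplitResult, TestCharacteristics, bayes_split
from .errors import InternalInconsistencyError, ValidationError

__all__ = [
    "CohortNode",
    "OutcomeProfile",
    "AggregatedRow",
    "expand",
    "aggregate_profiles",
    "trajectory",
    "level_counts",
    "profile_label",
    "DEFAULT_MAX_DEPTH",
    "PRUNE_BELOW",
]

#: Refuse expansions deeper than this by default (2**depth growth).
DEFAULT_MAX_DEPTH = 12

#: Branches with expected headcount below this are pruned as empty.
PRUNE_BELOW = 1e-12


def profile_label(n_positive: int, n_negative: int) -> str:
    """Canonical profile label: positives first, e.g. ``'++--'``."""
    return "+" * n_positive + "-" * n_negative


@dataclass
class CohortNode:
    """One node of the expansion tree.

    Leaves carry no split and no children; an internal node's children reuse
    its split outputs (positive child: ``n_pos`` / ``prevalence_pos``,
    negative child: ``n_neg`` / ``prevalence_neg``).  Empty branches are
    pruned.
    """

    state: CohortState
    split: Optional[SplitResult] = None
    pos: Optional["CohortNode"] = None
    neg: Optional["CohortNode"] = None

    def leaves(self) -> Iterator["CohortNode"]:
        if self.pos is None and self.neg is None:
            yield self
            return
        for child in (self.pos, self.neg):
            if child is not None:
                yield from child.leaves()


@dataclass(frozen=True)
class OutcomeProfile:
    """A (k positives out of n tests) outcome class with its multiplicity."""

    n_tests: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValidationError(f"n_tests must be >= 1, got {self.n_tests}")
        if not 0 <= self.n_positive <= self.n_tests:
            raise ValidationError(
                f"n_positive must lie in [0, {self.n_tests}], got {self.n_positive}"
            )

    @property
    def n_negative(self) -> int:
        return self.n_tests - self.n_positive

    @property
    def multiplicity(self) -> int:
        """Number of orderings sharing this profile, C(n_tests, n_positive)."""
        return math.comb(self.n_tests, self.n_positive)

    @property
    def label(self) -> str:
        return profile_label(self.n_positive, self.n_negative)


@dataclass(frozen=True)
class AggregatedRow:
    """Expected counts for one outcome profile, all orderings combined.

    ``posterior`` is P(sick | profile) = sick / concerned (``None`` for an
    empty profile).
    """

    profile: OutcomeProfile
    concerned: float
    sick: float
    healthy: float
    posterior: Optional[float]


def expand(
    root: CohortState,
    test: TestCharacteristics,
    depth: int,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> CohortNode:
    """Expand ``root`` into a full binary tree of the given depth.

    Raises
    ------
    ValidationError
        If ``depth`` is negative or exceeds ``max_depth``.
    """
    if int(depth) != depth or depth < 0:
        raise ValidationError(f"depth must be a nonnegative integer, got {depth!r}")
    if depth > max_depth:
        raise ValidationError(
            f"depth {depth} exceeds the configured maximum {max_depth} "
            f"(tree size grows as 2**depth)"
        )
    return _expand(root, test, int(depth))


def _expand(state: CohortState, test: TestCharacteristics, depth: int) -> CohortNode:
    node = CohortNode(state=state)
    if depth == 0 or state.size < PRUNE_BELOW:
        return node
    split = bayes_split(state, test)
    node.split = split
    if split.n_pos >= PRUNE_BELOW and split.prevalence_pos is not None:
        node.pos = _expand(
            CohortState(split.n_pos, split.prevalence_pos, state.profile_label + "+"),
            test,
            depth - 1,
        )
    if split.n_neg >= PRUNE_BELOW and split.prevalence_neg is not None:
        node.neg = _expand(
            CohortState(split.n_neg, split.prevalence_neg, state.profile_label + "-"),
            test,
            depth - 1,
        )
    return node


def _closed_form_counts(
    root: CohortState, test: TestCharacteristics, depth: int, k: int
) -> Tuple[float, float]:
    """Expected (sick, healthy) headcounts of the k-positives-of-depth profile."""
    n_sick = root.size * root.prevalence
    n_healthy = root.size - n_sick
    mult = math.comb(depth, k)
    sick = n_sick * mult * test.sensitivity**k * test.p_false_negative ** (depth - k)
    healthy = (
        n_healthy * mult * test.p_false_positive**k * test.specificity ** (depth - k)
    )
    return sick, healthy


def aggregate_profiles(
    root: CohortState,
    test: TestCharacteristics,
    depth: int,
    max_depth: int = DEFAULT_MAX_DEPTH,
    rtol: float = 1e-9,
) -> List[AggregatedRow]:
    """Aggregate the depth-``depth`` expansion by number of positive results.

    Returns ``depth + 1`` rows ordered from all-positive down to
    all-negative.  Each row is computed both by summing tree leaves over
    orderings and by the binomial closed form; the routes must agree to
    relative tolerance ``rtol``.
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1 for aggregation, got {depth!r}")
    node = expand(root, test, depth, max_depth=max_depth)

    tree_sick = [0.0] * (depth + 1)
    tree_healthy = [0.0] * (depth + 1)
    for leaf in node.leaves():
        label = leaf.state.profile_label
        k = label.count("+")
        sick = leaf.state.size * leaf.state.prevalence
        tree_sick[k] += sick
        tree_healthy[k] += leaf.state.size - sick

    rows: List[AggregatedRow] = []
    for k in range(depth, -1, -1):
        cf_sick, cf_healthy = _closed_form_counts(root, test, depth, k)
        for name, tree_val, cf_val in (
            ("sick", tree_sick[k], cf_sick),
            ("healthy", tree_healthy[k], cf_healthy),
        ):
            if not math.isclose(tree_val, cf_val, rel_tol=rtol, abs_tol=rtol):
                raise InternalInconsistencyError(
                    f"tree and closed-form {name} counts disagree for profile "
                    f"{k}/{depth}: {tree_val!r} vs {cf_val!r}"
                )
        concerned = cf_sick + cf_healthy
        posterior = cf_sick / concerned if concerned > 0 else None
        rows.append(
            AggregatedRow(
                profile=OutcomeProfile(n_tests=depth, n_positive=k),
                concerned=concerned,
                sick=cf_sick,
                healthy=cf_healthy,
                posterior=posterior,
            )
        )
    return rows


def trajectory(
    root_prevalence: float,
    test: TestCharacteristics,
    n_negatives: int,
    max_tests: int,
) -> List[Tuple[int, float]]:
    """Posterior trajectory at a fixed number of negative results.

    For each total test count ``t`` from ``n_negatives`` to ``max_tests``,
    returns ``(t, posterior)`` for the profile with ``t - n_negatives``
    positives and ``n_negatives`` negatives.  Monotone nondecreasing in
    ``t`` whenever ``lr_positive > 1``.
    """
    from .core_bayes import posterior_after_profile

    if n_negatives < 0 or max_tests < n_negatives:
        raise ValidationError(
            f"need 0 <= n_negatives <= max_tests, got {n_negatives!r}, {max_tests!r}"
        )
    return [
        (t, posterior_after_profile(root_prevalence, test, t - n_negatives, n_negatives))
        for t in range(n_negatives, max_tests + 1)
    ]


def level_counts(
    root: CohortState,
    test: TestCharacteristics,
    max_depth: int,
) -> pd.DataFrame:
    """Expected per-profile headcounts at every depth 1..``max_depth``.

    Returns a tidy frame with columns ``depth``, ``n_positive``, ``label``,
    ``concerned``, ``sick``, ``healthy``.  The all-positive count at depth d
    equals ``n_sick_root * sens**d + n_healthy_root * (1 - spec)**d``.
    """
    if max_depth < 1:
        raise ValidationError(f"max_depth must be >= 1, got {max_depth!r}")
    records = []
    for d in range(1, max_depth + 1):
        for k in range(d, -1, -1):
            sick, healthy = _closed_form_counts(root, test, d, k)
            records.append(
                {
                    "depth": d,
                    "n_positive": k,
                    "label": profile_label(k, d - k),
                    "concerned": sick + healthy,
                    "sick": sick,
                    "healthy": healthy,
                }
            )
    return pd.DataFrame.from_records(records)
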