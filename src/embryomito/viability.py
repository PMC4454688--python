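"""Viability threshold derivation, classification and cohort evaluation.

Among transferred euploid blastocysts, implantation is never observed above
a certain mtDNA quantity. The threshold model formalises this: a cutoff on
the assay scale (qPCR relative quantity or NGS mito percent) above which an
embryo is predicted non-viable. The cutoff can be fixed (0.003 for qPCR,
0.07% for NGS) or derived from a training cohort as the smallest multiple
of a rounding grid strictly above the largest value observed among
implanting embryos — by construction no training implanter exceeds it.

Evaluation reports the negative predictive value of the non-viability
prediction (share of above-cutoff embryos that indeed failed to implant),
the implantation rate among predicted-viable embryos, the overall rate, and
the share of non-implanters flagged by the cutoff. A blinded prospective
harness derives the threshold on training data only and evaluates it on a
disjoint test cohort.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .records import Outcome

DEFAULT_ROUNDING_GRID = 0.0005
DEFAULT_CUTOFFS = {"qpcr": 0.003, "ngs": 0.07}


class Prediction(str, enum.Enum):
    POTENTIALLY_VIABLE = "potentially_viable"
    PREDICTED_NONVIABLE = "predicted_nonviable"


@dataclass
class ThresholdModel:
    assay: str  # "qpcr" | "ngs"
    cutoff: float
    derivation: str = "fixed"  # "fixed" | "derived"
    training_max_implanter: float = float("nan")

    def __post_init__(self) -> None:
        if self.assay not in DEFAULT_CUTOFFS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.derivation == "derived" and not (
            self.cutoff > self.training_max_implanter
        ):
            raise ValueError("derived cutoff must exceed the training implanter maximum")

    @classmethod
    def fixed(cls, assay: str, cutoff: float | None = None) -> "ThresholdModel":
        return cls(assay=assay, cutoff=cutoff or DEFAULT_CUTOFFS[assay])


@dataclass
class CohortMetrics:
    n_transferred: int
    n_implanted: int
    n_above: int
    n_above_implanted: int
    npv: float | None  # percent; None when no embryo is above the cutoff
    rate_below: float | None  # implantation % among below-cutoff embryos
    rate_overall: float
    flagged_nonimplanter_fraction: float  # % of non-implanters above cutoff


def _as_outcome(outcome) -> Outcome:
    return outcome if isinstance(outcome, Outcome) else Outcome(outcome)


def derive_threshold(
    records: Sequence[tuple[float, object]],
    assay: str = "qpcr",
    rounding_grid: float = DEFAULT_ROUNDING_GRID,
) -> ThresholdModel:
    """Derive the cutoff from (value, outcome) training records.

    The cutoff is the smallest positive multiple of ``rounding_grid``
    strictly greater than the maximum value among implanted records, so no
    training implanter lies above it.
    """
    if rounding_grid <= 0:
        raise ValueError("rounding_grid must be positive")
    implanted = [v for v, o in records if _as_outcome(o) is Outcome.IMPLANTED]
    others = [v for v, o in records if _as_outcome(o) is not Outcome.IMPLANTED]
    if not implanted:
        raise ValueError(
            "no implanted records in training data; use a fixed threshold instead"
        )
    if not others:
        raise ValueError("training data needs at least one non-implanted record")
    max_implanter = max(implanted)
    k = math.floor(max_implanter / rounding_grid) + 1
    cutoff = k * rounding_grid
    while cutoff <= max_implanter:  # guard against float rounding at exact multiples
        k += 1
        cutoff = k * rounding_grid
    return ThresholdModel(
        assay=assay,
        cutoff=cutoff,
        derivation="derived",
        training_max_implanter=max_implanter,
    )


def classify(value: float, model: ThresholdModel) -> Prediction:
    """Predicted non-viable iff the value strictly exceeds the cutoff."""
    if not value > 0:
        raise ValueError("assay value must be positive")
    return (
        Prediction.PREDICTED_NONVIABLE
        if value > model.cutoff
        else Prediction.POTENTIALLY_VIABLE
    )


def evaluate_cohort(
    records: Sequence[tuple[float, object]], model: ThresholdModel
) -> CohortMetrics:
    """Compute outcome metrics for a cohort of (value, outcome) records.

    All outcomes must be known (implanted / not_implanted); filter unknowns
    upstream.
    """
    if not records:
        raise ValueError("empty cohort")
    outcomes = [_as_outcome(o) for _, o in records]
    if any(o is Outcome.UNKNOWN for o in outcomes):
        raise ValueError("cohort contains unknown outcomes; exclude them upstream")
    values = [v for v, _ in records]
    above = [o for v, o in zip(values, outcomes) if classify(v, model) is Prediction.PREDICTED_NONVIABLE]
    below = [o for v, o in zip(values, outcomes) if classify(v, model) is Prediction.POTENTIALLY_VIABLE]
    n = len(records)
    n_implanted = sum(o is Outcome.IMPLANTED for o in outcomes)
    n_above = len(above)
    n_above_implanted = sum(o is Outcome.IMPLANTED for o in above)
    n_below_implanted = n_implanted - n_above_implanted
    n_nonimplanted = n - n_implanted
    npv = 100.0 * (n_above - n_above_implanted) / n_above if n_above else None
    rate_below = 100.0 * n_below_implanted / len(below) if below else None
    flagged = (
        100.0 * sum(o is Outcome.NOT_IMPLANTED for o in above) / n_nonimplanted
        if n_nonimplanted
        else 0.0
    )
    return CohortMetrics(
        n_transferred=n,
        n_implanted=n_implanted,
        n_above=n_above,
        n_above_implanted=n_above_implanted,
        npv=npv,
        rate_below=rate_below,
        rate_overall=100.0 * n_implanted / n,
        flagged_nonimplanter_fraction=flagged,
    )


def blinded_validate(
    training: Sequence[tuple[str, float, object]],
    test: Sequence[tuple[str, float, object]],
    assay: str = "qpcr",
    rounding_grid: float = DEFAULT_ROUNDING_GRID,
    fixed_cutoff: float | None = None,
) -> tuple[ThresholdModel, CohortMetrics]:
    """Derive (or fix) a threshold on training data, evaluate on the test set.

    Records are (embryo_id, value, outcome); training and test must be
    disjoint by embryo_id, otherwise the blinding is violated and an error
    is raised. Test outcomes are only touched inside the evaluation.
    """
    train_ids = {r[0] for r in training}
    test_ids = {r[0] for r in test}
    overlap = train_ids & test_ids
    if overlap:
        raise ValueError(f"blinding violated: ids in both cohorts: {sorted(overlap)}")
    if fixed_cutoff is not None:
        model = ThresholdModel.fixed(assay, fixed_cutoff)
    else:
        model = derive_threshold([(v, o) for _, v, o in training], assay, rounding_grid)
    metrics = evaluate_cohort([(v, o) for _, v, o in test], model)
    return model, metrics
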