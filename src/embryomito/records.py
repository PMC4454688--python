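"""Core domain types shared across the pipeline.

An :class:`EmbryoRecord` describes one biopsied embryo: its identity,
maternal age, developmental stage (day-3 cleavage vs day-5/6 blastocyst),
ploidy status from comprehensive chromosome screening, transfer outcome,
and the latent mitochondrial quantities the synthetic generator plants
(``true_mt_rq`` on the qPCR relative-quantity scale, ``true_mt_fraction``
on the sequencing percent-of-aligned-bases scale, as a fraction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Stage(str, enum.Enum):
    CLEAVAGE = "cleavage"
    BLASTOCYST = "blastocyst"


class Ploidy(str, enum.Enum):
    EUPLOID = "euploid"
    ANEUPLOID = "aneuploid"


class Outcome(str, enum.Enum):
    IMPLANTED = "implanted"
    NOT_IMPLANTED = "not_implanted"
    UNKNOWN = "unknown"


@dataclass
class EmbryoRecord:
    """One embryo with its metadata and latent mitochondrial quantities.

    ``aneuploid_chromosomes`` lists ``(chromosome, copy_state)`` pairs with
    copy state 1 (monosomy) or 3 (trisomy); it is empty iff the embryo is
    euploid. Only euploid embryos are ever transferred, so an implanted
    outcome implies euploidy.
    """

    embryo_id: str
    maternal_age: int
    stage: Stage = Stage.BLASTOCYST
    ploidy: Ploidy = Ploidy.EUPLOID
    aneuploid_chromosomes: list[tuple[str, int]] = field(default_factory=list)
    outcome: Outcome = Outcome.UNKNOWN
    true_mt_rq: float = float("nan")
    true_mt_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if isinstance(self.stage, str):
            self.stage = Stage(self.stage)
        if isinstance(self.ploidy, str):
            self.ploidy = Ploidy(self.ploidy)
        if isinstance(self.outcome, str):
            self.outcome = Outcome(self.outcome)
        if (self.ploidy is Ploidy.EUPLOID) != (not self.aneuploid_chromosomes):
            raise ValueError(
                f"{self.embryo_id}: aneuploid_chromosomes must be empty "
                "iff the embryo is euploid"
            )
        for _, state in self.aneuploid_chromosomes:
            if state not in (1, 3):
                raise ValueError(f"{self.embryo_id}: copy state must be 1 or 3")
        if self.outcome is Outcome.IMPLANTED and self.ploidy is not Ploidy.EUPLOID:
            raise ValueError(
                f"{self.embryo_id}: only euploid embryos are transferred; "
                "an implanted embryo cannot be aneuploid"
            )
        if self.true_mt_rq == self.true_mt_rq and self.true_mt_rq <= 0:
            raise ValueError(f"{self.embryo_id}: true_mt_rq must be positive")
        if self.true_mt_fraction == self.true_mt_fraction and not (
            0.0 <= self.true_mt_fraction <= 1.0
        ):
            raise ValueError(f"{self.embryo_id}: true_mt_fraction must be in [0, 1]")
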