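"""Sporophytic self-incompatibility cross prediction and field scoring.

In sporophytic self-incompatibility (SSI) the pollen phenotype is set by
the diploid pollen parent, so dominance between the two carried S
haplotypes matters: Class I haplotypes are dominant over Class II, and
within-class heterozygotes express both alleles.  A flower-stage cross
fails whenever the two parents express a common S haplotype.  Bud
pollination bypasses the SI response entirely.

Field outcomes are scored by the compatibility index (seeds per pollinated
flower) and pod setting rate; index thresholds classify a cross as strongly
incompatible (< 0.5), weakly incompatible (0.5–2.0, boundaries included)
or compatible (> 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Stage",
    "ObservedClass",
    "SGenotype",
    "CrossOutcome",
    "CrossPrediction",
    "expressed_haplotypes",
    "predict_cross",
    "compatibility_index",
    "pod_rate",
    "classify_index",
    "concordance",
    "STRONG_INCOMPATIBLE_MAX",
    "COMPATIBLE_MIN",
]

STRONG_INCOMPATIBLE_MAX = 0.5  # exclusive upper bound of strong incompatibility
COMPATIBLE_MIN = 2.0           # exclusive lower bound of compatibility


class Stage(str, Enum):
    FLOWER = "flower"
    BUD = "bud"


class ObservedClass(str, Enum):
    STRONG_INCOMPATIBLE = "strong_incompatible"
    WEAK_INCOMPATIBLE = "weak_incompatible"
    COMPATIBLE = "compatible"


@dataclass(frozen=True)
class SGenotype:
    """A diploid genotype's one or two S haplotypes with class labels."""

    genotype_id: str
    haplotypes: frozenset[tuple[str, str]]  # (nau_name, si_class)

    def __post_init__(self) -> None:
        if len(self.haplotypes) not in (1, 2):
            raise ValueError(
                f"{self.genotype_id}: expected 1 or 2 haplotypes, "
                f"got {len(self.haplotypes)}"
            )
        names = {name for name, _ in self.haplotypes}
        if len(names) != len(self.haplotypes):
            raise ValueError(f"{self.genotype_id}: duplicate haplotype name")
        for _, si_class in self.haplotypes:
            if si_class not in ("class_I", "class_II"):
                raise ValueError(f"{self.genotype_id}: invalid class {si_class!r}")

    @property
    def is_heterozygous(self) -> bool:
        return len(self.haplotypes) == 2


@dataclass(frozen=True)
class CrossOutcome:
    female_id: str
    male_id: str
    n_flowers: int
    n_pods: int
    n_seeds: int

    def __post_init__(self) -> None:
        if self.n_flowers < 1:
            raise ValueError("n_flowers must be >= 1")
        if self.n_pods > self.n_flowers:
            raise ValueError(
                f"{self.female_id} x {self.male_id}: pods exceed flowers"
            )

    @property
    def compatibility_index(self) -> float:
        return compatibility_index(self.n_seeds, self.n_flowers)

    @property
    def pod_rate_pct(self) -> float:
        return pod_rate(self.n_pods, self.n_flowers)

    @property
    def observed_class(self) -> ObservedClass:
        return classify_index(self.compatibility_index)


@dataclass(frozen=True)
class CrossPrediction:
    female_id: str
    male_id: str
    predicted: str  # "incompatible" | "compatible"
    shared_expressed: frozenset[str]
    stage: Stage

    def __post_init__(self) -> None:
        if self.stage is Stage.BUD and self.predicted != "compatible":
            raise ValueError("bud pollination bypasses SI; must predict compatible")


def expressed_haplotypes(genotype: SGenotype) -> frozenset[str]:
    """S haplotypes a genotype expresses on stigma and pollen.

    Homozygotes express their single haplotype.  Within-class
    heterozygotes are co-dominant (both expressed); in a Class I/II
    heterozygote the Class I allele is dominant and alone is expressed.
    The same rule applies on both sides of a cross.
    """
    classes = {si_class for _, si_class in genotype.haplotypes}
    if classes == {"class_I", "class_II"}:
        return frozenset(
            name for name, si_class in genotype.haplotypes if si_class == "class_I"
        )
    return frozenset(name for name, _ in genotype.haplotypes)


def predict_cross(
    female: SGenotype, male: SGenotype, stage: Stage = Stage.FLOWER
) -> CrossPrediction:
    """Predict cross compatibility from shared expressed S haplotypes.

    Flower stage: incompatible iff the parents express a common haplotype
    (symmetric in the parents).  Bud stage: always compatible.
    """
    stage = Stage(stage)
    if stage is Stage.BUD:
        return CrossPrediction(
            female.genotype_id, male.genotype_id, "compatible", frozenset(), stage
        )
    shared = expressed_haplotypes(female) & expressed_haplotypes(male)
    predicted = "incompatible" if shared else "compatible"
    return CrossPrediction(female.genotype_id, male.genotype_id, predicted, shared, stage)


def compatibility_index(n_seeds: int, n_flowers: int) -> float:
    """Seeds per pollinated flower."""
    if n_flowers < 1:
        raise ValueError("n_flowers must be >= 1")
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    return n_seeds / n_flowers


def pod_rate(n_pods: int, n_flowers: int) -> float:
    """Pods per pollinated flower, as a percentage."""
    if n_flowers < 1:
        raise ValueError("n_flowers must be >= 1")
    if not 0 <= n_pods <= n_flowers:
        raise ValueError("n_pods must be in [0, n_flowers]")
    return 100.0 * n_pods / n_flowers


def classify_index(ci: float) -> ObservedClass:
    """Threshold classification of a compatibility index.

    Below 0.5: strong incompatibility; 0.5 through 2.0 (closed interval):
    weak incompatibility; above 2.0: compatibility.
    """
    if ci < 0:
        raise ValueError("compatibility index must be >= 0")
    if ci < STRONG_INCOMPATIBLE_MAX:
        return ObservedClass.STRONG_INCOMPATIBLE
    if ci <= COMPATIBLE_MIN:
        return ObservedClass.WEAK_INCOMPATIBLE
    return ObservedClass.COMPATIBLE


def concordance(
    predictions: Sequence[CrossPrediction],
    outcomes: Sequence[CrossOutcome],
) -> tuple[Optional[float], pd.DataFrame]:
    """Agreement between predicted and observed cross compatibility.

    The shared-haplotype model is binary, so observed strong and weak
    incompatibility both collapse to "incompatible" for scoring.  Crosses
    are matched on (female_id, male_id); every outcome must have a
    prediction.  Returns (agreement fraction or None when empty, per-cross
    table with a ``concordant`` column).
    """
    pred_index = {(p.female_id, p.male_id): p for p in predictions}
    rows = []
    for outcome in outcomes:
        key = (outcome.female_id, outcome.male_id)
        if key not in pred_index:
            raise KeyError(f"no prediction for cross {key[0]} x {key[1]}")
        prediction = pred_index[key]
        observed = outcome.observed_class
        observed_binary = (
            "compatible" if observed is ObservedClass.COMPATIBLE else "incompatible"
        )
        rows.append(
            {
                "female_id": outcome.female_id,
                "male_id": outcome.male_id,
                "predicted": prediction.predicted,
                "compatibility_index": outcome.compatibility_index,
                "pod_rate_pct": outcome.pod_rate_pct,
                "observed_class": observed.value,
                "concordant": prediction.predicted == observed_binary,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "female_id", "male_id", "predicted", "compatibility_index",
            "pod_rate_pct", "observed_class", "concordant",
        ],
    )
    agreement = float(table["concordant"].mean()) if len(table) else None
    return agreement, table
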