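"""Comparison specifications over histotype / stage-group strata.

Three kinds of two-group contrast are used throughout the package:

* ``one_vs_rest`` — one histotype against the other histotypes combined,
  within a stage group (early = FIGO I/II, late = III/IV);
* ``pairwise`` — one histotype against another, within a stage group;
* ``stage_within_histotype`` — early against late within one histotype.

The full plan enumerates 4 histotypes x 2 stage groups one-vs-rest, all 6
histotype pairs x 2 stage groups, and 4 within-histotype stage contrasts
(24 comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .data_io import HISTOTYPES, SampleMetadata, ValidationError

STAGE_GROUPS = ("early", "late")


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group contrast resolved against sample metadata.

    ``target`` and ``reference`` are (histotype, stage_group) selectors;
    ``None`` in the histotype slot of the reference of a one-vs-rest
    contrast means "all other histotypes".
    """

    kind: str  # one_vs_rest | pairwise | stage_within_histotype
    target_histotype: str
    target_stage_group: str | None
    reference_histotype: str | None = None
    reference_stage_group: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("one_vs_rest", "pairwise", "stage_within_histotype"):
            raise ValueError(f"unknown comparison kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "one_vs_rest":
            return f"{self.target_histotype}_{self.target_stage_group}_vs_rest"
        if self.kind == "pairwise":
            return (f"{self.target_histotype}_vs_{self.reference_histotype}"
                    f"_{self.target_stage_group}")
        return f"{self.target_histotype}_early_vs_late"

    def resolve(self, metadata: SampleMetadata) -> tuple[list[str], list[str]]:
        """Target and reference sample-id sets (disjoint, label-driven)."""
        if self.kind == "one_vs_rest":
            target = metadata.select(histotype=self.target_histotype,
                                     stage_group=self.target_stage_group)
            reference = [s for h in HISTOTYPES if h != self.target_histotype
                         for s in metadata.select(histotype=h,
                                                  stage_group=self.target_stage_group)]
        elif self.kind == "pairwise":
            target = metadata.select(histotype=self.target_histotype,
                                     stage_group=self.target_stage_group)
            reference = metadata.select(histotype=self.reference_histotype,
                                        stage_group=self.target_stage_group)
        else:  # stage_within_histotype: early vs late
            target = metadata.select(histotype=self.target_histotype, stage_group="early")
            reference = metadata.select(histotype=self.target_histotype, stage_group="late")
        if set(target) & set(reference):
            raise ValidationError(f"{self.label}: target and reference overlap")
        return target, reference


def one_vs_rest(histotype: str, stage_group: str) -> ComparisonSpec:
    return ComparisonSpec("one_vs_rest", histotype, stage_group)


def pairwise(target: str, reference: str, stage_group: str) -> ComparisonSpec:
    return ComparisonSpec("pairwise", target, stage_group, reference_histotype=reference)


def stage_within(histotype: str) -> ComparisonSpec:
    return ComparisonSpec("stage_within_histotype", histotype, None)


def full_comparison_plan() -> list[ComparisonSpec]:
    """The complete stratified plan: 8 one-vs-rest, 12 pairwise, 4 stage contrasts."""
    plan: list[ComparisonSpec] = []
    for sg in STAGE_GROUPS:
        for h in HISTOTYPES:
            plan.append(one_vs_rest(h, sg))
    for sg in STAGE_GROUPS:
        for h1, h2 in combinations(HISTOTYPES, 2):
            plan.append(pairwise(h1, h2, sg))
    for h in HISTOTYPES:
        plan.append(stage_within(h))
    return plan
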