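"""Representative-association selection and reproducibility classification.

Many variants were tested repeatedly within a population by overlapping
follow-up studies, so for each (variant, population) a single *representative*
association is kept: the result from the study with the most case subjects.
Representatives are then classified:

* **inter-population reproduced** — significant, direction-consistent
  representatives in at least two different geographical populations;
* **intra-population reproduced** — a significant representative replicated by
  an independent (distinct publication) significant study in the same
  population;
* **unconfirmed** — everything else, including variants whose reports point in
  opposite directions (the same allele deleterious in one population and
  protective in another is treated as a failure to replicate, not a
  replication).

Direction comparison harmonizes allele labels first: the reverse-strand
complement of an allele counts as the same allele, and when two reports name
the two different alleles of a biallelic marker their odds ratios must fall on
opposite sides of 1 to agree. Reports lacking an odds ratio (or with OR
exactly 1) are direction-indeterminate and never veto a classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .core import (
    AssociationRecord,
    GradeLevel,
    MarkerLocus,
    PopulationLabel,
    SignificanceGrade,
    ValidationError,
    check_locus_partition,
)
from .grading import grade

__all__ = [
    "RepresentativeAssociation",
    "Direction",
    "ReproClass",
    "ReproducibilityCall",
    "select_representatives",
    "harmonize_direction",
    "classify_inter",
    "classify_intra",
    "count_loci",
]


@dataclass(frozen=True)
class RepresentativeAssociation:
    """The representative record for one (variant, population), with its grade."""

    record: AssociationRecord
    grade: SignificanceGrade


class Direction(str, Enum):
    CONSISTENT = "consistent"
    CONFLICTING = "conflicting"
    INDETERMINATE = "indeterminate"


class ReproClass(str, Enum):
    INTER_POPULATION = "inter_population"
    INTRA_POPULATION = "intra_population"
    UNCONFIRMED = "unconfirmed"


@dataclass(frozen=True)
class ReproducibilityCall:
    variant_id: str
    klass: ReproClass
    supporting: tuple[tuple[str, PopulationLabel, GradeLevel], ...] = ()
    locus_id: Optional[str] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.klass is ReproClass.INTER_POPULATION:
            populations = {pop for _, pop, _ in self.supporting}
            if len(self.supporting) < 2 or len(populations) < 2:
                raise ValidationError(
                    f"{self.variant_id}: inter-population call requires >=2 supporting "
                    f"associations from >=2 populations"
                )


def _representative_sort_key(record: AssociationRecord):
    # max n_cases, then min p_value, then max n_controls, then study_id
    return (-record.n_cases, record.p_value, -record.n_controls, record.study_id)


def select_representatives(
    records: list[AssociationRecord],
) -> list[RepresentativeAssociation]:
    """Pick one representative per (variant, population): largest case count wins.

    Ties break by smaller P-value, then larger control count, then
    lexicographic study_id, so the choice is deterministic under any input
    ordering. Output is sorted by (variant_id, population).
    """
    groups: dict[tuple[str, PopulationLabel], list[AssociationRecord]] = {}
    for record in records:
        groups.setdefault((record.variant_id, record.population), []).append(record)
    representatives = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].value)):
        best = min(groups[key], key=_representative_sort_key)
        representatives.append(RepresentativeAssociation(record=best, grade=grade(best)))
    return representatives


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _same_allele(a: str, b: str) -> bool:
    a, b = a.upper(), b.upper()
    return a == b or _COMPLEMENT.get(a) == b


def _direction_of(
    allele_a: Optional[str],
    or_a: Optional[float],
    allele_b: Optional[str],
    or_b: Optional[float],
) -> Direction:
    if or_a is None or or_b is None or or_a == 1.0 or or_b == 1.0:
        return Direction.INDETERMINATE
    same_side = (or_a > 1.0) == (or_b > 1.0)
    if allele_a is not None and allele_b is not None:
        if _same_allele(allele_a, allele_b):
            return Direction.CONSISTENT if same_side else Direction.CONFLICTING
        # the two reports name the two alleles of the pair: ORs must invert
        return Direction.CONFLICTING if same_side else Direction.CONSISTENT
    return Direction.CONSISTENT if same_side else Direction.CONFLICTING


def harmonize_direction(
    a: RepresentativeAssociation, b: RepresentativeAssociation
) -> Direction:
    """Decide whether two reports of one variant agree on effect direction."""
    if a.record.variant_id != b.record.variant_id:
        raise ValidationError(
            f"direction comparison across variants: "
            f"{a.record.variant_id} vs {b.record.variant_id}"
        )
    return _direction_of(
        a.record.risk_allele,
        a.record.odds_ratio,
        b.record.risk_allele,
        b.record.odds_ratio,
    )


def _support_entry(rep: RepresentativeAssociation):
    return (rep.record.study_id, rep.record.population, rep.grade.level)


def classify_inter(
    representatives: list[RepresentativeAssociation],
) -> list[ReproducibilityCall]:
    """Classify each variant's cross-population reproducibility.

    A variant is inter-population reproduced when its significant
    representatives span at least two populations and no pair of them
    conflicts in direction. A variant with any conflicting pair is excluded
    (unconfirmed, with the conflict recorded in the call's note). One call is
    emitted per variant, sorted by variant_id.
    """
    by_variant: dict[str, list[RepresentativeAssociation]] = {}
    for rep in representatives:
        by_variant.setdefault(rep.record.variant_id, []).append(rep)
    calls = []
    for variant_id in sorted(by_variant):
        significant = sorted(
            (rep for rep in by_variant[variant_id] if rep.grade.is_significant),
            key=lambda rep: rep.record.population.value,
        )
        conflict = None
        for i, rep_a in enumerate(significant):
            for rep_b in significant[i + 1 :]:
                if harmonize_direction(rep_a, rep_b) is Direction.CONFLICTING:
                    conflict = (rep_a, rep_b)
                    break
            if conflict:
                break
        populations = {rep.record.population for rep in significant}
        if conflict is not None:
            calls.append(
                ReproducibilityCall(
                    variant_id=variant_id,
                    klass=ReproClass.UNCONFIRMED,
                    note=(
                        "direction conflict between "
                        f"{conflict[0].record.population.value} and "
                        f"{conflict[1].record.population.value}"
                    ),
                )
            )
        elif len(populations) >= 2:
            calls.append(
                ReproducibilityCall(
                    variant_id=variant_id,
                    klass=ReproClass.INTER_POPULATION,
                    supporting=tuple(_support_entry(rep) for rep in significant),
                )
            )
        else:
            calls.append(
                ReproducibilityCall(variant_id=variant_id, klass=ReproClass.UNCONFIRMED)
            )
    return calls


def classify_intra(
    representatives: list[RepresentativeAssociation],
    all_records: list[AssociationRecord],
) -> list[ReproducibilityCall]:
    """Classify each variant's within-population reproducibility.

    For every (variant, population) whose representative is significant, look
    for at least one other record from a distinct publication in the same
    population that is also significant under its own regime and does not
    conflict in direction with the representative. One call per variant.
    """
    by_group: dict[tuple[str, PopulationLabel], list[AssociationRecord]] = {}
    for record in all_records:
        by_group.setdefault((record.variant_id, record.population), []).append(record)

    by_variant: dict[str, list[RepresentativeAssociation]] = {}
    for rep in representatives:
        by_variant.setdefault(rep.record.variant_id, []).append(rep)

    calls = []
    for variant_id in sorted(by_variant):
        supporting: list[tuple[str, PopulationLabel, GradeLevel]] = []
        for rep in sorted(
            by_variant[variant_id], key=lambda r: r.record.population.value
        ):
            if not rep.grade.is_significant:
                continue
            group = by_group.get((variant_id, rep.record.population), [])
            replications = []
            for other in group:
                if other.study_id == rep.record.study_id:
                    continue
                other_grade = grade(other)
                if not other_grade.is_significant:
                    continue
                direction = _direction_of(
                    rep.record.risk_allele,
                    rep.record.odds_ratio,
                    other.risk_allele,
                    other.odds_ratio,
                )
                if direction is not Direction.CONFLICTING:
                    replications.append((other, other_grade))
            if replications:
                supporting.append(_support_entry(rep))
                supporting.extend(
                    (other.study_id, other.population, g.level)
                    for other, g in sorted(replications, key=lambda t: t[0].study_id)
                )
        calls.append(
            ReproducibilityCall(
                variant_id=variant_id,
                klass=ReproClass.INTRA_POPULATION if supporting else ReproClass.UNCONFIRMED,
                supporting=tuple(supporting),
            )
        )
    return calls


def count_loci(calls: list[ReproducibilityCall], loci: list[MarkerLocus]) -> int:
    """Count distinct loci among confirmed (non-unconfirmed) variants.

    A confirmed variant missing from the locus map is an error: the locus
    count is meaningless when signals cannot be deduplicated.
    """
    assignment = check_locus_partition(loci)
    locus_ids = set()
    for call in calls:
        if call.klass is ReproClass.UNCONFIRMED:
            continue
        locus_id = call.locus_id or assignment.get(call.variant_id)
        if locus_id is None:
            raise ValidationError(
                f"confirmed variant {call.variant_id} has no locus assignment"
            )
        locus_ids.add(locus_id)
    return len(locus_ids)
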