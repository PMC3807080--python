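"""Domain model and population taxonomy.

Association evidence for rheumatoid arthritis (RA) is curated at the level of
one reported result per (variant, study, population). Studies are grouped into
nine geographical populations; the grouping drives the reproducibility
classification, so an unrecognized population label is a hard error rather
than a silent pass-through.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "ValidationError",
    "PopulationLabel",
    "Coverage",
    "StudyDesign",
    "GradeLevel",
    "Regime",
    "SignificanceGrade",
    "AssociationRecord",
    "MarkerLocus",
    "resolve_population",
]


class ValidationError(ValueError):
    """A domain object or input row violated a validation rule."""


class PopulationLabel(str, Enum):
    """The nine canonical geographical populations used for grouping."""

    EUROPEAN = "European"
    EAST_ASIAN = "EastAsian"
    WEST_ASIAN = "WestAsian"
    SOUTH_ASIAN = "SouthAsian"
    SOUTH_AMERICAN = "SouthAmerican"
    CENTRAL_AMERICAN = "CentralAmerican"
    NORTH_AFRICAN = "NorthAfrican"
    SOUTH_AFRICAN = "SouthAfrican"
    AFRICAN_AMERICAN = "AfricanAmerican"


class Coverage(str, Enum):
    """Whether a study assayed genome-wide SNPs or a selected few."""

    GENOME_WIDE = "genome_wide"
    SELECTED = "selected"


class StudyDesign(str, Enum):
    GWAS = "gwas"
    FOLLOWUP = "followup"
    META_OF_GWAS = "meta_of_gwas"
    COMBINED_GWAS_REPLICATION = "combined_gwas_replication"


class GradeLevel(str, Enum):
    """Evidence strength verdict; ordered strong > moderate > not significant."""

    STRONG = "strong"
    MODERATE = "moderate"
    NOT_SIGNIFICANT = "not_significant"

    @property
    def rank(self) -> int:
        return {"strong": 2, "moderate": 1, "not_significant": 0}[self.value]

    @property
    def is_significant(self) -> bool:
        return self is not GradeLevel.NOT_SIGNIFICANT


class Regime(str, Enum):
    """Which pair of significance thresholds applies to a study."""

    GENOME_WIDE = "genome_wide"
    FOLLOWUP = "followup"


@dataclass(frozen=True)
class SignificanceGrade:
    level: GradeLevel
    regime: Regime

    @property
    def is_significant(self) -> bool:
        return self.level.is_significant


def _load_synonym_table() -> dict[str, PopulationLabel]:
    """Build the normalized synonym -> canonical lookup from the shipped config."""
    text = resources.files("ravarkit.data").joinpath("population_synonyms.yaml").read_text()
    raw = yaml.safe_load(text)
    table: dict[str, PopulationLabel] = {}
    for canonical, synonyms in raw.items():
        label = PopulationLabel(canonical)
        for syn in [canonical, *synonyms]:
            key = _normalize_label(syn)
            if key in table and table[key] is not label:
                raise ValidationError(
                    f"population synonym {syn!r} maps to both {table[key].value} and {label.value}"
                )
            table[key] = label
    return table


def _normalize_label(raw: str) -> str:
    return re.sub(r"[\s_\-]+", " ", raw.strip()).lower()


_SYNONYMS: Optional[dict[str, PopulationLabel]] = None


def resolve_population(raw_label: str) -> PopulationLabel:
    """Resolve a free-text population label to its canonical group.

    Lookup is case-insensitive and whitespace/hyphen-normalized (so
    ``"South-East Asian"``, ``"south east asian"`` and ``"SouthEast Asian"``
    all resolve alike). Unknown labels raise :class:`ValidationError`; the
    grouping semantics are too load-bearing to guess.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonym_table()
    if not raw_label or not raw_label.strip():
        raise ValidationError("population label must be non-empty")
    key = _normalize_label(raw_label)
    # camel-case canonical spellings ("EastAsian") normalize without a space
    if key not in _SYNONYMS:
        spaced = _normalize_label(re.sub(r"(?<=[a-z])(?=[A-Z])", " ", raw_label.strip()))
        if spaced in _SYNONYMS:
            key = spaced
    try:
        return _SYNONYMS[key]
    except KeyError:
        raise ValidationError(f"unknown population label: {raw_label!r}") from None


@dataclass(frozen=True)
class AssociationRecord:
    """One reported variant-study-population association.

    ``risk_allele`` is the allele whose odds ratio is reported (it may be
    protective, OR < 1, when the source reports the minor allele).
    ``odds_ratio`` is allelic and refers to ``risk_allele``. Optional fields
    are ``None`` when the source did not print them.
    """

    study_id: str
    variant_id: str
    p_value: float
    n_cases: int
    n_controls: int
    population: PopulationLabel
    coverage: Coverage
    design: StudyDesign
    risk_allele: Optional[str] = None
    odds_ratio: Optional[float] = None
    phenotype_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"{self.variant_id}/{self.study_id}: p_value must be in (0, 1], got {self.p_value!r}"
            )
        if self.odds_ratio is not None and not self.odds_ratio > 0:
            raise ValidationError(
                f"{self.variant_id}/{self.study_id}: odds_ratio must be > 0, got {self.odds_ratio!r}"
            )
        if not isinstance(self.n_cases, int) or self.n_cases < 1:
            raise ValidationError(
                f"{self.variant_id}/{self.study_id}: n_cases must be a positive integer, got {self.n_cases!r}"
            )
        if not isinstance(self.n_controls, int) or self.n_controls < 1:
            raise ValidationError(
                f"{self.variant_id}/{self.study_id}: n_controls must be a positive integer, got {self.n_controls!r}"
            )
        if not isinstance(self.population, PopulationLabel):
            raise ValidationError(f"population must be a PopulationLabel, got {self.population!r}")
        if not isinstance(self.coverage, Coverage):
            raise ValidationError(f"coverage must be a Coverage, got {self.coverage!r}")
        if not isinstance(self.design, StudyDesign):
            raise ValidationError(f"design must be a StudyDesign, got {self.design!r}")
        if self.risk_allele is not None and not self.risk_allele:
            raise ValidationError("risk_allele, when present, must be non-empty")

    @property
    def key(self) -> tuple[str, str, PopulationLabel]:
        """The identity of a record within one association table."""
        return (self.variant_id, self.study_id, self.population)


@dataclass(frozen=True)
class MarkerLocus:
    """A group of tightly linked markers counted as one independent signal."""

    locus_id: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus_id must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))


def check_locus_partition(loci: list[MarkerLocus]) -> dict[str, str]:
    """Return variant_id -> locus_id, rejecting variants claimed by two loci."""
    assignment: dict[str, str] = {}
    for locus in loci:
        for variant in locus.members:
            prior = assignment.get(variant)
            if prior is not None and prior != locus.locus_id:
                raise ValidationError(
                    f"variant {variant} assigned to loci {prior} and {locus.locus_id}"
                )
            assignment[variant] = locus.locus_id
    return assignment
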