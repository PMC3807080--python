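"""Synthetic association tables with planted reproducibility classes.

The generator emulates the multi-study, multi-population literature the
curation pipeline consumes: for each requested variant it plants study records
whose P-values, odds ratios, alleles, populations and case counts force a
known reproducibility outcome, so the classifier can be scored against exact
ground truth. Planted P-values sit an order of magnitude beyond the decision
thresholds (1e-9 vs 5e-8 genome-wide; 1e-3 vs 0.01 follow-up) so recovery
tests never ride a boundary; threshold boundaries are exercised separately by
the grading tests.

Planted classes:

* ``inter_reproduced`` — significant, direction-consistent representatives in
  two or more populations.
* ``intra_reproduced`` — two or more independent significant studies in a
  single population.
* ``lone_significant`` — a single significant study, nothing to replicate it.
* ``never_significant`` — only non-significant reports.
* ``direction_conflict`` — significant in two populations but with the same
  allele on opposite sides of OR 1, which excludes the variant.
* ``small_study_only`` — a significant small study displaced by a larger
  non-significant study, so the representative itself is non-significant.

P-values are planted, not sampled from simulated cohorts, and no LD structure
is simulated (each variant is its own locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AssociationRecord,
    Coverage,
    MarkerLocus,
    PopulationLabel,
    StudyDesign,
    ValidationError,
)
from .grading import grade
from .reproducibility import (
    ReproClass,
    classify_inter,
    classify_intra,
    select_representatives,
)
from .risk import RiskMarker

__all__ = [
    "PLANTED_CLASSES",
    "SynthSpec",
    "simulate_association_table",
    "simulate_loci",
    "simulate_genotype",
    "recover_classes",
]

PLANTED_CLASSES = (
    "inter_reproduced",
    "intra_reproduced",
    "lone_significant",
    "never_significant",
    "direction_conflict",
    "small_study_only",
)

# planted P-values, one order of magnitude past each decision threshold
_P_SIG = {Coverage.GENOME_WIDE: 1e-9, Coverage.SELECTED: 1e-3}
_P_NONSIG = {Coverage.GENOME_WIDE: 1e-3, Coverage.SELECTED: 0.5}

_ALLELES = ("A", "C", "G", "T")
_OR_RANGE = (1.05, 2.5)  # log-uniform magnitude range for risk-variant ORs


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic association table."""

    inter_reproduced: int = 3
    intra_reproduced: int = 4
    lone_significant: int = 3
    never_significant: int = 5
    direction_conflict: int = 2
    small_study_only: int = 2
    populations: tuple[PopulationLabel, ...] = (
        PopulationLabel.EUROPEAN,
        PopulationLabel.EAST_ASIAN,
        PopulationLabel.SOUTH_ASIAN,
    )
    studies_per_variant: tuple[int, int] = (2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in PLANTED_CLASSES:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} count must be >= 0")
        if not self.populations:
            raise ValidationError("at least one population is required")
        if len(set(self.populations)) < 2 and (
            self.inter_reproduced > 0 or self.direction_conflict > 0
        ):
            raise ValidationError(
                "inter_reproduced and direction_conflict classes need >= 2 populations"
            )
        lo, hi = self.studies_per_variant
        if not 1 <= lo <= hi:
            raise ValidationError(f"invalid studies_per_variant range {self.studies_per_variant}")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")


class _Emitter:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._variant_n = 0
        self._study_n = 0

    def variant(self) -> str:
        self._variant_n += 1
        return f"rs{9_000_000 + self._variant_n}"

    def study(self) -> str:
        self._study_n += 1
        return f"S{self._study_n:05d}"

    def odds_ratio(self) -> float:
        lo, hi = np.log(_OR_RANGE)
        return float(np.exp(self.rng.uniform(lo, hi)))

    def record(
        self,
        variant: str,
        population: PopulationLabel,
        significant: bool,
        odds_ratio: float,
        allele: str,
        n_cases: int,
    ) -> AssociationRecord:
        genome_wide = bool(self.rng.integers(2))
        coverage = Coverage.GENOME_WIDE if genome_wide else Coverage.SELECTED
        return AssociationRecord(
            study_id=self.study(),
            variant_id=variant,
            risk_allele=allele,
            p_value=(_P_SIG if significant else _P_NONSIG)[coverage],
            odds_ratio=odds_ratio,
            n_cases=n_cases,
            n_controls=int(self.rng.integers(1000, 30000)),
            population=population,
            coverage=coverage,
            design=StudyDesign.GWAS if genome_wide else StudyDesign.FOLLOWUP,
        )


def simulate_association_table(
    spec: SynthSpec,
) -> tuple[list[AssociationRecord], dict[str, str]]:
    """Emit (records, truth) where truth maps variant_id -> planted class."""
    rng = np.random.default_rng(spec.seed)
    emit = _Emitter(rng)
    pops = list(dict.fromkeys(spec.populations))
    lo, hi = spec.studies_per_variant
    records: list[AssociationRecord] = []
    truth: dict[str, str] = {}

    def pick_pops(k: int) -> list[PopulationLabel]:
        idx = rng.choice(len(pops), size=k, replace=False)
        return [pops[i] for i in sorted(idx)]

    for _ in range(spec.inter_reproduced):
        variant = emit.variant()
        allele = _ALLELES[rng.integers(4)]
        k = int(rng.integers(2, len(set(pops)) + 1))
        for population in pick_pops(k):
            records.append(
                emit.record(variant, population, True, emit.odds_ratio(), allele,
                            int(rng.integers(2000, 6000)))
            )
        truth[variant] = "inter_reproduced"

    for _ in range(spec.intra_reproduced):
        variant = emit.variant()
        allele = _ALLELES[rng.integers(4)]
        population = pops[rng.integers(len(pops))]
        n_studies = int(rng.integers(max(2, lo), hi + 1))
        cases = sorted(rng.integers(500, 6000, size=n_studies), reverse=True)
        for n_cases in cases:
            records.append(
                emit.record(variant, population, True, emit.odds_ratio(), allele, int(n_cases))
            )
        truth[variant] = "intra_reproduced"

    for _ in range(spec.lone_significant):
        variant = emit.variant()
        population = pops[rng.integers(len(pops))]
        records.append(
            emit.record(variant, population, True, emit.odds_ratio(),
                        _ALLELES[rng.integers(4)], int(rng.integers(500, 6000)))
        )
        truth[variant] = "lone_significant"

    for _ in range(spec.never_significant):
        variant = emit.variant()
        allele = _ALLELES[rng.integers(4)]
        n_studies = int(rng.integers(lo, hi + 1))
        for _ in range(n_studies):
            population = pops[rng.integers(len(pops))]
            records.append(
                emit.record(variant, population, False, emit.odds_ratio(), allele,
                            int(rng.integers(500, 6000)))
            )
        truth[variant] = "never_significant"

    for _ in range(spec.direction_conflict):
        variant = emit.variant()
        allele = _ALLELES[rng.integers(4)]
        odds_ratio = emit.odds_ratio()
        pop_a, pop_b = pick_pops(2)
        # same allele, opposite sides of OR 1, both significant
        records.append(
            emit.record(variant, pop_a, True, odds_ratio, allele, int(rng.integers(2000, 6000)))
        )
        records.append(
            emit.record(variant, pop_b, True, 1.0 / odds_ratio, allele,
                        int(rng.integers(2000, 6000)))
        )
        truth[variant] = "direction_conflict"

    for _ in range(spec.small_study_only):
        variant = emit.variant()
        allele = _ALLELES[rng.integers(4)]
        population = pops[rng.integers(len(pops))]
        odds_ratio = emit.odds_ratio()
        # significant small study displaced by a larger non-significant one
        records.append(
            emit.record(variant, population, True, odds_ratio, allele, int(rng.integers(100, 400)))
        )
        records.append(
            emit.record(variant, population, False, odds_ratio, allele,
                        int(rng.integers(5000, 9000)))
        )
        truth[variant] = "small_study_only"

    return records, truth


def simulate_loci(truth: dict[str, str]) -> list[MarkerLocus]:
    """One singleton locus per simulated variant (no LD structure)."""
    return [
        MarkerLocus(locus_id=f"L_{variant}", members=frozenset({variant}))
        for variant in sorted(truth)
    ]


def simulate_genotype(panel: list[RiskMarker], seed: int) -> dict[str, int]:
    """Draw risk-allele copy numbers under Hardy-Weinberg equilibrium."""
    for marker in panel:
        if not 0.0 < marker.p < 1.0:
            raise ValidationError(
                f"{marker.variant_id}: HWE sampling needs 0 < p < 1, got {marker.p}"
            )
    rng = np.random.default_rng(seed)
    return {m.variant_id: int(rng.binomial(2, m.p)) for m in panel}


def recover_classes(records: list[AssociationRecord]) -> dict[str, str]:
    """Run the full classification pipeline and map each variant back onto the
    planted-class taxonomy (the inverse of :func:`simulate_association_table`).
    """
    representatives = select_representatives(records)
    inter = {c.variant_id: c for c in classify_inter(representatives)}
    intra = {c.variant_id: c for c in classify_intra(representatives, records)}

    sig_rep_variants = {
        rep.record.variant_id for rep in representatives if rep.grade.is_significant
    }
    rep_keys = {(rep.record.variant_id, rep.record.study_id) for rep in representatives}
    shadowed_sig = {
        r.variant_id
        for r in records
        if (r.variant_id, r.study_id) not in rep_keys and grade(r).is_significant
    }

    recovered: dict[str, str] = {}
    for variant in sorted({r.variant_id for r in records}):
        if inter[variant].klass is ReproClass.INTER_POPULATION:
            recovered[variant] = "inter_reproduced"
        elif intra[variant].klass is ReproClass.INTRA_POPULATION:
            recovered[variant] = "intra_reproduced"
        elif variant in sig_rep_variants:
            if inter[variant].note:
                recovered[variant] = "direction_conflict"
            else:
                recovered[variant] = "lone_significant"
        elif variant in shadowed_sig:
            recovered[variant] = "small_study_only"
        else:
            recovered[variant] = "never_significant"
    return recovered
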