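"""Re-evaluation of published association evidence under two significance regimes.

A study that assayed genome-wide SNPs is held to genome-wide thresholds
(strong: P < 5e-8; moderate: 5e-8 <= P <= 1e-5), while a follow-up study that
assayed only a few SNPs of interest is held to nominal thresholds (strong:
P < 0.01; moderate: 0.01 <= P <= 0.05). Meta-analyses of GWAS and combined
GWAS + replication analyses are judged at genome-wide thresholds regardless of
their nominal coverage. Boundary handling: "strong" is strictly below the
stringent threshold, "moderate" is the closed interval up to and including the
weak threshold, "not significant" is strictly above it.
"""

from __future__ import annotations

from .core import (
    AssociationRecord,
    Coverage,
    GradeLevel,
    Regime,
    SignificanceGrade,
    StudyDesign,
)

__all__ = ["THRESHOLDS", "select_regime", "grade_p_value", "grade"]

# regime -> (strong bound, weak bound); strong below the first,
# moderate up to and including the second, not significant above.
THRESHOLDS: dict[Regime, tuple[float, float]] = {
    Regime.GENOME_WIDE: (5.0e-8, 1.0e-5),
    Regime.FOLLOWUP: (0.01, 0.05),
}

_GENOME_WIDE_DESIGNS = frozenset(
    {StudyDesign.GWAS, StudyDesign.META_OF_GWAS, StudyDesign.COMBINED_GWAS_REPLICATION}
)


def select_regime(record: AssociationRecord) -> Regime:
    """Choose the threshold regime for one record.

    Design is consulted first (a meta-analysis of GWAS or a combined
    GWAS + replication analysis is judged genome-wide even when it reports a
    selected-SNP panel), then coverage; anything else is a follow-up study.
    """
    if record.design in _GENOME_WIDE_DESIGNS:
        return Regime.GENOME_WIDE
    if record.coverage is Coverage.GENOME_WIDE:
        return Regime.GENOME_WIDE
    return Regime.FOLLOWUP


def grade_p_value(p_value: float, regime: Regime) -> GradeLevel:
    """Grade a published P-value under the given regime's thresholds."""
    strong_below, weak_upto = THRESHOLDS[regime]
    if p_value < strong_below:
        return GradeLevel.STRONG
    if p_value <= weak_upto:
        return GradeLevel.MODERATE
    return GradeLevel.NOT_SIGNIFICANT


def grade(record: AssociationRecord) -> SignificanceGrade:
    """Grade one association record; a pure function of (p_value, regime)."""
    regime = select_regime(record)
    return SignificanceGrade(level=grade_p_value(record.p_value, regime), regime=regime)
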