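"""Weighted genetic risk score and relative genetic risk.

A risk marker i carries an allelic odds ratio r_i (the risk factor), a risk
allele frequency p_i measured in controls, and an individual's risk-allele
copy number X_i in {0, 1, 2}. Two indices are computed over a panel of
independent (LD-pruned) markers:

* **GRS** — the weighted genetic risk score, additive in log odds ratios:
  GRS = sum_i X_i * ln(r_i). Baseline 0 corresponds to a carrier of no risk
  alleles.
* **RGR** — the relative genetic risk. Per marker, the genotype-specific risk
  is s_i = r_i^{X_i}; the population-average risk under Hardy–Weinberg
  equilibrium is a_i = p_i^2 r_i^2 + 2 p_i (1 - p_i) r_i + (1 - p_i)^2, so
  RGR_i = s_i / a_i and the overall RGR is the product over markers. By
  construction E[RGR_i] = 1 over HWE genotypes: 1.0 means an average
  individual of the population.

Lifetime risk is the overall RGR multiplied by the population disease
prevalence, capped at 1.

Markers in the same LD block would double-count one signal, so panels are
pruned to the single smallest-P marker per locus before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .core import PopulationLabel, ValidationError

__all__ = [
    "RiskMarker",
    "RiskResult",
    "DEFAULT_PREVALENCE",
    "prune_ld",
    "grs",
    "marker_rgr",
    "overall_rgr",
    "lifetime_risk",
    "copy_number",
    "predict",
]

# Population disease prevalence used as the lifetime-risk baseline (RA in the
# general European population is about 1%); user-overridable per call.
DEFAULT_PREVALENCE: dict[PopulationLabel, float] = {
    PopulationLabel.EUROPEAN: 0.01,
}


@dataclass(frozen=True)
class RiskMarker:
    """A confirmed risk marker entering the prediction panel."""

    variant_id: str
    risk_allele: str
    r: float  # allelic odds ratio of the risk allele
    p: float  # risk allele frequency in controls
    p_value: float
    locus_id: str
    population: PopulationLabel

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if not self.risk_allele:
            raise ValidationError(f"{self.variant_id}: risk_allele must be non-empty")
        if not self.r > 0:
            raise ValidationError(f"{self.variant_id}: odds ratio must be > 0, got {self.r!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(
                f"{self.variant_id}: risk allele frequency must be in [0, 1], got {self.p!r}"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"{self.variant_id}: p_value must be in (0, 1], got {self.p_value!r}"
            )
        if not self.locus_id:
            raise ValidationError(f"{self.variant_id}: locus_id must be non-empty")


# genotype: variant_id -> risk-allele copy number; None/absent = missing
GenotypeInput = Mapping[str, Optional[int]]


@dataclass(frozen=True)
class RiskResult:
    grs: float
    per_marker_rgr: dict[str, float]
    overall_rgr: float
    lifetime_risk: float
    n_markers_used: int
    prevalence: float


def prune_ld(markers: list[RiskMarker]) -> list[RiskMarker]:
    """Keep the single marker with the smallest association P-value per locus.

    Ties break lexicographically by variant_id; output is ordered by locus_id.
    """
    best: dict[str, RiskMarker] = {}
    for marker in markers:
        incumbent = best.get(marker.locus_id)
        if incumbent is None or (marker.p_value, marker.variant_id) < (
            incumbent.p_value,
            incumbent.variant_id,
        ):
            best[marker.locus_id] = marker
    return [best[locus_id] for locus_id in sorted(best)]


def _check_genotype(marker: RiskMarker, x: int) -> None:
    if x not in (0, 1, 2):
        raise ValidationError(
            f"{marker.variant_id}: copy number must be 0, 1 or 2, got {x!r}"
        )
    if marker.p == 0.0 and x > 0:
        raise ValidationError(
            f"{marker.variant_id}: risk allele frequency 0 is incompatible with carrying it"
        )
    if marker.p == 1.0 and x < 2:
        raise ValidationError(
            f"{marker.variant_id}: risk allele frequency 1 is incompatible with X={x}"
        )


def grs(markers: list[RiskMarker], genotype: GenotypeInput) -> float:
    """Weighted genetic risk score: sum of X_i * ln(r_i) over typed markers."""
    total = 0.0
    for marker in markers:
        x = genotype.get(marker.variant_id)
        if x is None:
            continue
        _check_genotype(marker, x)
        total += x * math.log(marker.r)
    return total


def marker_rgr(marker: RiskMarker, x: int) -> float:
    """Relative genetic risk of one marker genotype.

    s = r^X over the HWE population-average risk
    a = p^2 r^2 + 2 p (1 - p) r + (1 - p)^2.
    """
    _check_genotype(marker, x)
    r, p = marker.r, marker.p
    s = r**x
    a = p * p * r * r + 2.0 * p * (1.0 - p) * r + (1.0 - p) ** 2
    return s / a


def overall_rgr(markers: list[RiskMarker], genotype: GenotypeInput) -> float:
    """Product of per-marker RGRs over typed markers (empty panel -> 1)."""
    product = 1.0
    for marker in markers:
        x = genotype.get(marker.variant_id)
        if x is None:
            continue
        product *= marker_rgr(marker, x)
    return product


def lifetime_risk(rgr: float, prevalence: float) -> float:
    """Overall RGR times population prevalence, capped at 1."""
    if not 0.0 < prevalence < 1.0:
        raise ValidationError(f"prevalence must be in (0, 1), got {prevalence!r}")
    if not rgr > 0:
        raise ValidationError(f"overall RGR must be positive, got {rgr!r}")
    return min(rgr * prevalence, 1.0)


def copy_number(marker: RiskMarker, genotype_string: str) -> int:
    """Risk-allele copy number from a two-letter genotype string (e.g. "AG")."""
    alleles = [a.upper() for a in genotype_string.strip()]
    if len(alleles) != 2:
        raise ValidationError(
            f"{marker.variant_id}: genotype must be two alleles, got {genotype_string!r}"
        )
    for allele in alleles:
        if allele not in {"A", "C", "G", "T"}:
            raise ValidationError(
                f"{marker.variant_id}: unknown allele {allele!r} in genotype {genotype_string!r}"
            )
    return sum(allele == marker.risk_allele.upper() for allele in alleles)


def predict(
    markers: list[RiskMarker],
    genotype: GenotypeInput,
    prevalence: float,
    prune: bool = True,
) -> RiskResult:
    """Full risk prediction for one individual over a marker panel.

    Markers are LD-pruned first (unless the panel is already pruned), markers
    with missing genotypes are skipped (no imputation), and n_markers_used
    reports how many actually contributed.
    """
    panel = prune_ld(markers) if prune else list(markers)
    per_marker: dict[str, float] = {}
    for marker in panel:
        x = genotype.get(marker.variant_id)
        if x is None:
            continue
        per_marker[marker.variant_id] = marker_rgr(marker, x)
    rgr = math.prod(per_marker.values()) if per_marker else 1.0
    return RiskResult(
        grs=grs(panel, genotype),
        per_marker_rgr=per_marker,
        overall_rgr=rgr,
        lifetime_risk=lifetime_risk(rgr, prevalence),
        n_markers_used=len(per_marker),
        prevalence=prevalence,
    )
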