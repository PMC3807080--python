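import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ravarkit import (
    GradeLevel,
    PopulationLabel,
    SynthSpec,
    ValidationError,
    grade,
    recover_classes,
    select_representatives,
    simulate_association_table,
    simulate_genotype,
    simulate_loci,
)
from ravarkit.risk import overall_rgr

from conftest import make_marker

THREE_POPS = (
    PopulationLabel.EUROPEAN,
    PopulationLabel.EAST_ASIAN,
    PopulationLabel.SOUTH_ASIAN,
)


class TestSimulateAssociationTable:
    def test_planted_classes_recovered(self):
        spec = SynthSpec(inter_reproduced=3, intra_reproduced=4, never_significant=5, seed=7)
        records, truth = simulate_association_table(spec)
        assert recover_classes(records) == truth

    def test_empty_spec_gives_empty_table(self):
        spec = SynthSpec(0, 0, 0, 0, 0, 0, populations=THREE_POPS, seed=1)
        records, truth = simulate_association_table(spec)
        assert records == [] and truth == {}

    def test_small_study_only_representative_not_significant(self):
        """The planted small significant study is displaced by a larger
        non-significant one, so the variant's representative fails grading."""
        spec = SynthSpec(0, 0, 0, 0, 0, small_study_only=4, seed=3)
        records, truth = simulate_association_table(spec)
        reps = select_representatives(records)
        assert len(reps) == 4
        for rep in reps:
            assert rep.grade.level is GradeLevel.NOT_SIGNIFICANT
        shadowed = [r for r in records if grade(r).is_significant]
        assert len(shadowed) == 4

    def test_deterministic_given_seed(self):
        spec = SynthSpec(seed=11)
        assert simulate_association_table(spec) == simulate_association_table(spec)

    def test_impossible_spec_rejected(self):
        with pytest.raises(ValidationError):
            SynthSpec(inter_reproduced=1, populations=(PopulationLabel.EUROPEAN,))
        with pytest.raises(ValidationError):
            SynthSpec(inter_reproduced=-1)

    @given(
        counts=st.lists(st.integers(0, 4), min_size=6, max_size=6),
        seed=st.integers(0, 10_000),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_label_recovery_property(self, counts, seed):
        """Whatever the planted mix, the pipeline recovers it exactly."""
        spec = SynthSpec(*counts, populations=THREE_POPS, seed=seed)
        records, truth = simulate_association_table(spec)
        assert recover_classes(records) == truth

    def test_loci_are_singletons(self):
        _, truth = simulate_association_table(SynthSpec(seed=5))
        loci = simulate_loci(truth)
        assert len(loci) == len(truth)
        assert all(len(l.members) == 1 for l in loci)


class TestSimulateGenotype:
    def test_deterministic_given_seed(self, five_marker_panel):
        assert simulate_genotype(five_marker_panel, 42) == simulate_genotype(
            five_marker_panel, 42
        )

    def test_homozygote_frequency_matches_hwe(self):
        """For a high-frequency allele, the X=2 rate is within 3 sigma of p^2."""
        p = 0.9
        marker = make_marker(p=p)
        n = 4000
        hits = sum(
            simulate_genotype([marker], seed)[marker.variant_id] == 2
            for seed in range(n)
        )
        expected = n * p * p
        sigma = np.sqrt(n * p * p * (1 - p * p))
        assert abs(hits - expected) <= 3 * sigma

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValidationError):
            simulate_genotype([make_marker(p=0.0)], 1)

    def test_mean_overall_rgr_is_one(self, five_marker_panel):
        """Monte-Carlo mean of the overall relative risk over HWE genotypes
        converges to the average-population baseline of 1."""
        rng = np.random.default_rng(123)
        n = 20_000
        values = np.ones(n)
        for marker in five_marker_panel:
            draws = rng.binomial(2, marker.p, size=n)
            per_genotype = np.array(
                [overall_rgr([marker], {marker.variant_id: x}) for x in (0, 1, 2)]
            )
            values *= per_genotype[draws]
        se = values.std(ddof=1) / np.sqrt(n)
        assert abs(values.mean() - 1.0) <= 3 * se
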