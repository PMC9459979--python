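"""SSI dominance, cross prediction and compatibility-index classification."""

import itertools

import pytest

from stype.genetics import (
    CrossOutcome,
    ObservedClass,
    SGenotype,
    Stage,
    classify_index,
    compatibility_index,
    concordance,
    expressed_haplotypes,
    pod_rate,
    predict_cross,
)


def hom(gid, name, si_class="class_I"):
    return SGenotype(gid, frozenset({(name, si_class)}))


def het(gid, pairs):
    return SGenotype(gid, frozenset(pairs))


class TestExpressedHaplotypes:
    def test_homozygote_expresses_its_haplotype(self):
        assert expressed_haplotypes(hom("g", "NAU-S25")) == {"NAU-S25"}

    def test_class_I_over_class_II_dominance(self):
        genotype = het("g", [("NAU-S17", "class_I"), ("NAU-S39", "class_II")])
        assert expressed_haplotypes(genotype) == {"NAU-S17"}

    def test_within_class_codominance(self):
        both_I = het("g", [("NAU-S16", "class_I"), ("NAU-S25", "class_I")])
        assert expressed_haplotypes(both_I) == {"NAU-S16", "NAU-S25"}
        both_II = het("g", [("NAU-S39", "class_II"), ("NAU-S52", "class_II")])
        assert expressed_haplotypes(both_II) == {"NAU-S39", "NAU-S52"}

    def test_rule_table_enumeration(self):
        """Dominance agrees with exhaustive enumeration of the rule table."""
        for c1, c2 in itertools.product(["class_I", "class_II"], repeat=2):
            genotype = het("g", [("A", c1), ("B", c2)]) if ("A", c1) != ("B", c2) \
                else hom("g", "A", c1)
            expressed = expressed_haplotypes(genotype)
            assert expressed
            assert expressed <= {name for name, _ in genotype.haplotypes}
            if {c1, c2} == {"class_I", "class_II"}:
                assert expressed == {n for n, c in genotype.haplotypes if c == "class_I"}

    def test_genotype_invariants(self):
        with pytest.raises(ValueError):
            SGenotype("g", frozenset())
        with pytest.raises(ValueError):
            SGenotype("g", frozenset({("A", "class_I"), ("A", "class_II")}))


class TestPredictCross:
    def test_same_haplotype_cross_incompatible(self):
        prediction = predict_cross(hom("Rs4", "NAU-S25"), hom("Rs40", "NAU-S25"))
        assert prediction.predicted == "incompatible"
        assert prediction.shared_expressed == {"NAU-S25"}

    def test_different_haplotypes_compatible(self):
        prediction = predict_cross(hom("Rs4", "NAU-S25"), hom("Rs32", "NAU-S14"))
        assert prediction.predicted == "compatible"
        assert prediction.shared_expressed == frozenset()

    def test_bud_stage_bypasses_si(self):
        prediction = predict_cross(hom("Rs4", "NAU-S25"), hom("Rs4", "NAU-S25"),
                                   Stage.BUD)
        assert prediction.predicted == "compatible"

    def test_flower_stage_symmetric_in_parents(self):
        a = het("a", [("NAU-S17", "class_I"), ("NAU-S39", "class_II")])
        b = hom("b", "NAU-S39", "class_II")
        forward = predict_cross(a, b)
        backward = predict_cross(b, a)
        assert forward.predicted == backward.predicted == "compatible"

    def test_masked_class_II_allele_does_not_block(self):
        # the Class II allele of a I/II heterozygote is not expressed,
        # so sharing it with the partner does not cause rejection
        a = het("a", [("NAU-S17", "class_I"), ("NAU-S39", "class_II")])
        b = hom("b", "NAU-S39", "class_II")
        assert predict_cross(a, b).predicted == "compatible"


class TestIndices:
    @pytest.mark.parametrize("seeds,flowers,index", [(0, 20, 0.0), (47, 100, 0.47),
                                                     (75, 20, 3.75)])
    def test_compatibility_index(self, seeds, flowers, index):
        assert compatibility_index(seeds, flowers) == pytest.approx(index)

    def test_zero_flowers_rejected(self):
        with pytest.raises(ValueError):
            compatibility_index(5, 0)

    @pytest.mark.parametrize("pods,flowers,rate", [(10, 40, 25.0), (0, 15, 0.0),
                                                   (79, 100, 79.0)])
    def test_pod_rate(self, pods, flowers, rate):
        assert pod_rate(pods, flowers) == pytest.approx(rate)

    def test_more_pods_than_flowers_rejected(self):
        with pytest.raises(ValueError):
            pod_rate(41, 40)


class TestClassifyIndex:
    @pytest.mark.parametrize(
        "index,expected",
        [
            (0.88, ObservedClass.WEAK_INCOMPATIBLE),
            (0.52, ObservedClass.WEAK_INCOMPATIBLE),
            (0.20, ObservedClass.STRONG_INCOMPATIBLE),
            (0.17, ObservedClass.STRONG_INCOMPATIBLE),
            (0.47, ObservedClass.STRONG_INCOMPATIBLE),
            (0.37, ObservedClass.STRONG_INCOMPATIBLE),
            (3.76, ObservedClass.COMPATIBLE),
            (3.08, ObservedClass.COMPATIBLE),
            (2.83, ObservedClass.COMPATIBLE),
            (2.05, ObservedClass.COMPATIBLE),
            (1.85, ObservedClass.WEAK_INCOMPATIBLE),
            # boundaries fall in the closed weak interval
            (0.5, ObservedClass.WEAK_INCOMPATIBLE),
            (2.0, ObservedClass.WEAK_INCOMPATIBLE),
        ],
    )
    def test_thresholds(self, index, expected):
        assert classify_index(index) is expected

    def test_monotone_ordering(self):
        order = [ObservedClass.STRONG_INCOMPATIBLE, ObservedClass.WEAK_INCOMPATIBLE,
                 ObservedClass.COMPATIBLE]
        grid = [x / 100 for x in range(0, 400, 7)]
        ranks = [order.index(classify_index(x)) for x in grid]
        assert ranks == sorted(ranks)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_index(-0.1)


# The published pollination experiment: 11 crosses among typed lines,
# with (female, female haplotypes), (male, male haplotypes), flowers scaled
# to 100 so seeds/pods reproduce the printed index and pod rate.
GENOTYPES = {
    "Rs1": hom("Rs1", "NAU-S51"),
    "Rs4": hom("Rs4", "NAU-S25"),
    "Rs5": hom("Rs5", "NAU-S17"),
    "Rs7": hom("Rs7", "NAU-S16"),
    "Rs9": hom("Rs9", "NAU-S16"),
    "Rs16": hom("Rs16", "NAU-S16"),
    "Rs18": hom("Rs18", "NAU-S15"),
    "Rs24": hom("Rs24", "NAU-S44"),
    "Rs30": hom("Rs30", "NAU-S05"),
    "Rs34": hom("Rs34", "NAU-S15"),
    "Rs38": hom("Rs38", "NAU-S17"),
    "Rs40": hom("Rs40", "NAU-S25"),
    "Rs44": hom("Rs44", "NAU-S44"),
}

CROSSES = [
    # female, male, compatibility index, pod rate (%)
    ("Rs5", "Rs38", 0.88, 27.57),
    ("Rs44", "Rs24", 0.52, 24.09),
    ("Rs7", "Rs9", 0.20, 12.07),
    ("Rs7", "Rs16", 0.17, 12.09),
    ("Rs4", "Rs40", 0.47, 19.75),
    ("Rs40", "Rs4", 0.37, 21.79),
    ("Rs1", "Rs40", 3.76, 78.93),
    ("Rs44", "Rs30", 3.08, 74.64),
    ("Rs34", "Rs40", 2.83, 67.90),
    ("Rs7", "Rs18", 1.85, 72.98),
    ("Rs7", "Rs1", 2.05, 71.75),
]


def study_outcomes():
    return [
        CrossOutcome(f, m, 100, round(rate), round(ci * 100))
        for f, m, ci, rate in CROSSES
    ]


class TestConcordance:
    def test_study_crosses_agree_except_the_weak_different_haplotype_row(self):
        predictions = [
            predict_cross(GENOTYPES[f], GENOTYPES[m]) for f, m, _, _ in CROSSES
        ]
        agreement, table = concordance(predictions, study_outcomes())
        assert agreement == pytest.approx(10 / 11)
        discordant = table[~table["concordant"]]
        assert len(discordant) == 1
        row = discordant.iloc[0]
        # the one miss: different-haplotype cross observed weakly incompatible
        assert (row.female_id, row.male_id) == ("Rs7", "Rs18")
        assert row.compatibility_index == pytest.approx(1.85)

    def test_reciprocal_crosses_get_one_prediction(self):
        forward = predict_cross(GENOTYPES["Rs4"], GENOTYPES["Rs40"])
        backward = predict_cross(GENOTYPES["Rs40"], GENOTYPES["Rs4"])
        assert forward.predicted == backward.predicted
        assert forward.shared_expressed == backward.shared_expressed

    def test_empty_inputs_give_absent_agreement(self):
        agreement, table = concordance([], [])
        assert agreement is None
        assert table.empty

    def test_all_concordant_synthetic_set(self):
        predictions = [predict_cross(GENOTYPES["Rs4"], GENOTYPES["Rs40"])]
        outcomes = [CrossOutcome("Rs4", "Rs40", 30, 5, 3)]
        agreement, _ = concordance(predictions, outcomes)
        assert agreement == 1.0

    def test_unmatched_cross_rejected(self):
        with pytest.raises(KeyError):
            concordance([], [CrossOutcome("x", "y", 10, 1, 1)])
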