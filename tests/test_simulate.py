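"""The synthetic panel generator: determinism, planted structure, noise model."""

import numpy as np
import pytest

from stype.amplify import SIClass, default_primer_pairs, virtual_pcr
from stype.genetics import SGenotype, Stage, classify_index
from stype.rflp import digest, find_sites
from stype.simulate import (
    SimulationConfig,
    class_I_tally_composition,
    simulate_genotype_panel,
    simulate_pollination,
    simulate_reference_panel,
    study_composition,
)
from stype.typing import percent_identity


class TestConfig:
    def test_divergence_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(between_divergence=0.01, within_divergence=0.05)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_I_fraction=1.5)


class TestReferencePanel:
    def test_deterministic_from_seed(self, sim_config, reference_panel):
        references, truth = reference_panel
        again, truth2 = simulate_reference_panel(SimulationConfig(rng_seed=11))
        assert [(r.nau_name, r.sequence) for r in again] == [
            (r.nau_name, r.sequence) for r in references
        ]
        assert truth2 == truth

    def test_every_reference_amplifies_with_its_own_pair_only(self, reference_panel):
        references, truth = reference_panel
        pairs = default_primer_pairs()
        for ref in references:
            own = pairs[SIClass(ref.si_class)]
            other = pairs[
                SIClass.CLASS_II if ref.si_class == "class_I" else SIClass.CLASS_I
            ]
            amps = virtual_pcr(ref.nau_name, ref.sequence, own)
            assert len(amps) == 1
            span = truth[ref.nau_name]
            assert (amps[0].start, amps[0].end) == (
                span.amplicon_start, span.amplicon_end,
            )
            assert virtual_pcr(ref.nau_name, ref.sequence, other) == []

    def test_amplicon_lengths_match_published_bands(self, reference_panel):
        references, truth = reference_panel
        for ref in references:
            span = truth[ref.nau_name]
            expected = 1200 if ref.si_class == "class_I" else 1000
            assert span.amplicon_end - span.amplicon_start == expected

    def test_planted_cut_map_is_the_true_cut_map(self, reference_panel):
        references, truth = reference_panel
        for ref in references:
            span = truth[ref.nau_name]
            amplicon = ref.sequence[span.amplicon_start : span.amplicon_end]
            observed = {span.amplicon_start + c for c in find_sites(amplicon)}
            planted = set(span.cut_positions)
            if ref.si_class == "class_I":
                # the reverse primer itself carries one constant GANTC
                assert planted <= observed
                assert len(observed - planted) == 1
            else:
                assert planted == set()

    def test_class_I_cut_maps_are_pairwise_distinct(self, reference_panel):
        references, truth = reference_panel
        maps = [
            truth[r.nau_name].cut_positions
            for r in references
            if r.si_class == "class_I"
        ]
        assert len(set(maps)) == len(maps) == 19

    def test_pairwise_identity_below_between_divergence_bound(self):
        config = SimulationConfig(n_haplotypes=6, class_I_fraction=1.0, rng_seed=7)
        references, _ = simulate_reference_panel(config)
        for i, a in enumerate(references):
            for b in references[i + 1 :]:
                assert percent_identity(a.sequence, b.sequence) <= 95.0

    def test_infeasible_site_map_request_rejected(self):
        config = SimulationConfig(
            n_haplotypes=40, class_I_fraction=1.0, n_hinfI_sites=(1, 1), rng_seed=0
        )
        with pytest.raises(ValueError, match="lattice"):
            simulate_reference_panel(config)


class TestGenotypePanel:
    def test_study_composition_counts(self, study_panel):
        classes = []
        for genotype in study_panel.truth.values():
            kinds = sorted(c for _, c in genotype.haplotypes)
            classes.append(tuple(kinds))
        assert classes.count(("class_I",)) == 48
        assert classes.count(("class_II",)) == 13
        assert classes.count(("class_I", "class_II")) == 17
        # one off-target material has sequences but no planted haplotype truth
        assert len(study_panel.sequences) == 79
        assert len(study_panel.truth) == 78

    def test_zero_within_divergence_copies_references(self, reference_panel):
        references, _ = reference_panel
        config = SimulationConfig(rng_seed=11, within_divergence=0.0,
                                  between_divergence=0.05)
        panel = simulate_genotype_panel(
            references, config, [("hom", references[0].nau_name)]
        )
        (name, seq), = panel.sequences["Rs1"]
        assert seq == references[0].sequence

    def test_within_divergence_stays_near_reference(
        self, reference_panel, study_panel, sim_config
    ):
        references, _ = reference_panel
        by_name = {r.nau_name: r for r in references}
        genotype_id, records = next(iter(study_panel.sequences.items()))
        name, seq = records[0]
        identity = percent_identity(seq, by_name[name].sequence)
        assert 100 - 100 * sim_config.within_divergence * 1.5 <= identity < 100.5

    def test_heterozygotes_emit_two_records(self, study_panel):
        for genotype_id, genotype in study_panel.truth.items():
            assert len(study_panel.sequences[genotype_id]) == len(genotype.haplotypes)

    def test_class_I_tally_composition_counts(self, reference_panel):
        references, _ = reference_panel
        composition = class_I_tally_composition(references)
        assert len(composition) == 48
        names = [entry[1] for entry in composition]
        assert len(set(names)) == 19
        counts = sorted((names.count(n) for n in set(names)), reverse=True)
        assert counts == [8, 7, 5, 4, 4, 3, 3, 2, 2] + [1] * 10


def simple_truth():
    return {
        "a": SGenotype("a", frozenset({("NAU-S1", "class_I")})),
        "b": SGenotype("b", frozenset({("NAU-S1", "class_I")})),
        "c": SGenotype("c", frozenset({("NAU-S2", "class_I")})),
    }


class TestPollination:
    def test_large_sample_means_recover_compatibility_state(self):
        config = SimulationConfig(rng_seed=3, n_flowers_per_cross=10_000)
        records = simulate_pollination(
            simple_truth(), [("a", "b", "flower"), ("a", "c", "flower")], config
        )
        incompatible, compatible = records
        assert incompatible.n_seeds / incompatible.n_flowers == pytest.approx(0.2, rel=0.2)
        assert compatible.n_seeds / compatible.n_flowers == pytest.approx(3.0, rel=0.1)
        assert classify_index(incompatible.n_seeds / 10_000).value == "strong_incompatible"
        assert classify_index(compatible.n_seeds / 10_000).value == "compatible"

    def test_bud_stage_self_is_compatible(self):
        config = SimulationConfig(rng_seed=3)
        (record,) = simulate_pollination(simple_truth(), [("a", "a", Stage.BUD)], config)
        assert record.true_compatible

    def test_noise_free_mode_pins_the_index(self):
        config = SimulationConfig(rng_seed=3, n_flowers_per_cross=30)
        (record,) = simulate_pollination(
            simple_truth(), [("a", "c", "flower")], config, noise=False
        )
        assert record.n_seeds / record.n_flowers == pytest.approx(3.0)

    def test_unknown_genotype_rejected(self):
        config = SimulationConfig(rng_seed=3)
        with pytest.raises(KeyError):
            simulate_pollination(simple_truth(), [("a", "zzz", "flower")], config)

    def test_classification_recovery_rate_at_field_scale(self):
        """At 30 flowers per cross the index classifier recovers the true
        compatibility state for >= 95% of crosses."""
        config = SimulationConfig(rng_seed=5, n_flowers_per_cross=30)
        rng = np.random.default_rng(17)
        truth = simple_truth()
        ids = list(truth)
        crosses = [
            (ids[rng.integers(3)], ids[rng.integers(3)], "flower") for _ in range(200)
        ]
        records = simulate_pollination(truth, crosses, config)
        hits = 0
        for record in records:
            observed = classify_index(record.n_seeds / record.n_flowers)
            observed_compatible = observed.value == "compatible"
            hits += observed_compatible == record.true_compatible
        assert hits / len(records) >= 0.95
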