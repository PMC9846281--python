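"""Generators: determinism, planted-truth recovery, rate-parameter fidelity."""

import warnings

import numpy as np
import pytest

from mitochar.annotation import gene_table, spacer_summary
from mitochar.composition import base_composition
from mitochar.errors import ComputeError
from mitochar.model import feature_sequence
from mitochar.selection import gene_kaks
from mitochar.synthetic import (
    RECTORIS_LAYOUT,
    AlignmentSpec,
    FeaturePlan,
    GenomeSpec,
    generate_codon_alignment,
    generate_mitogenome,
)


class TestGenomeGenerator:
    def test_default_layout_counts_and_length(self, synth_genome):
        genome, truth = synth_genome
        assert genome.length == 16592
        assert genome.class_counts() == {
            "PCG": 13, "tRNA": 22, "rRNA": 2, "noncoding": 2}
        assert truth["length"] == 16592

    def test_same_seed_is_byte_identical(self):
        a, _ = generate_mitogenome(GenomeSpec(seed=9))
        b, _ = generate_mitogenome(GenomeSpec(seed=9))
        assert a.seq == b.seq and a.features == b.features
        c, _ = generate_mitogenome(GenomeSpec(seed=10))
        assert c.seq != a.seq

    def test_all_planted_discrete_truths_recovered(self, synth_genome):
        """Characterising the generated genome recovers every planted start
        codon, stop token, strand and spacer exactly."""
        genome, truth = synth_genome
        rows = gene_table(genome)
        assert [r.spacer_to_next for r in rows] == truth["spacer_to_next"]
        by_name = {r.name: r for r in rows if r.cls == "PCG"}
        for name, planted in truth["pcg"].items():
            row = by_name[name]
            assert row.start_codon == planted["start_codon"], name
            assert row.stop_codon == planted["stop_token"], name
            assert row.strand == planted["strand"], name

    def test_no_internal_stops_in_any_planted_gene(self, synth_genome):
        genome, _ = synth_genome
        stops = {"TAA", "TAG", "AGA", "AGG"}
        for f in genome.features_of_class("PCG"):
            sense = feature_sequence(genome, f)
            inner = [sense[i:i + 3] for i in range(3, 3 * (len(sense) // 3) - 3, 3)]
            assert not stops & set(inner), f.name

    def test_composition_within_three_se_of_generative_expectation(self):
        for seed in (0, 1, 2):
            genome, truth = generate_mitogenome(GenomeSpec(seed=seed))
            comp = base_composition(genome.seq)
            obs = {"A": comp.count_a, "C": comp.count_c,
                   "G": comp.count_g, "T": comp.count_t}
            for base in "ACGT":
                z = (obs[base] - truth["expected_base_counts"][base]) / \
                    truth["sd_base_counts"][base]
                assert abs(z) < 3, (seed, base, z)

    def test_planted_overlap_plan_round_trips(self, synth_genome):
        """The layout plants the published overlap/IGN structure; the
        characterisation summary reads it back."""
        genome, _ = synth_genome
        s = spacer_summary(genome)
        assert (s.n_overlaps, s.overlap_max) == (10, 7)
        assert (s.n_ign, s.ign_total, s.ign_max) == (17, 84, 24)

    def test_single_planted_overlap(self):
        layout = (
            FeaturePlan("g1", "PCG", 1, 99, "H", None, "ATG", "TAA"),
            FeaturePlan("t1", "tRNA", 93, 160, "H", "GAA"),
            FeaturePlan("g2", "PCG", 161, 259, "H", None, "ATG", "TAA"),
        )
        genome, _ = generate_mitogenome(
            GenomeSpec(length=300, layout=layout, seed=4))
        s = spacer_summary(genome)
        assert s.n_overlaps == 1 and s.overlap_max == 7

    def test_inconsistent_stop_plan_rejected(self):
        layout = (FeaturePlan("g", "PCG", 1, 99, "H", None, "ATG", "T--"),)
        with pytest.raises(ComputeError, match="stop plan"):
            generate_mitogenome(GenomeSpec(length=200, layout=layout, seed=0))

    def test_infeasible_lock_collision_rejected(self):
        # two H-strand genes whose start codons demand different bases at
        # one position: gene h2's ATG overlaps h1's planted TAA stop
        # h2's ATG needs position 30 = 'T', h1's TAA stop needs it = 'A'
        layout = (
            FeaturePlan("h1", "PCG", 1, 30, "H", None, "ATG", "TAA"),
            FeaturePlan("h2", "PCG", 29, 58, "H", None, "ATG", "TAA"),
        )
        with pytest.raises(ComputeError, match="infeasible"):
            generate_mitogenome(GenomeSpec(length=100, layout=layout, seed=0))


class TestAlignmentGenerator:
    def test_zero_branch_length_gives_identical_rows(self):
        aln, _ = generate_codon_alignment(
            AlignmentSpec(n_taxa=5, n_codons=50, branch_length=0.0, seed=1))
        assert len(set(aln.rows)) == 1

    def test_same_seed_is_identical(self):
        a, _ = generate_codon_alignment(AlignmentSpec(seed=6, n_codons=60))
        b, _ = generate_codon_alignment(AlignmentSpec(seed=6, n_codons=60))
        assert a.rows == b.rows
        c, _ = generate_codon_alignment(AlignmentSpec(seed=7, n_codons=60))
        assert c.rows != a.rows

    def test_rows_are_stop_free_and_in_frame(self):
        aln, _ = generate_codon_alignment(AlignmentSpec(seed=2, n_codons=80))
        stops = {"TAA", "TAG", "AGA", "AGG"}
        for row in aln.rows:
            assert len(row) % 3 == 0
            assert not stops & {row[i:i + 3] for i in range(0, len(row), 3)}

    def test_realized_substitution_mix_tracks_omega(self):
        """Across replicates, the realized nonsynonymous fraction of
        substitutions stays within binomial noise of the process's expected
        flux fraction, and moves with omega."""
        fractions = {}
        for omega in (0.1, 1.0):
            syn = non = 0
            expected = None
            for rep in range(10):
                _, truth = generate_codon_alignment(AlignmentSpec(
                    n_taxa=6, n_codons=300, omega=omega, seed=100 + rep))
                syn += truth["realized_syn_substitutions"]
                non += truth["realized_nonsyn_substitutions"]
                expected = truth["expected_nonsyn_fraction"]
            total = syn + non
            frac = non / total
            se = (expected * (1 - expected) / total) ** 0.5
            assert abs(frac - expected) < 4 * se, (omega, frac, expected)
            fractions[omega] = frac
        assert fractions[0.1] < fractions[1.0]

    def test_neutral_simulation_estimates_near_one(self):
        """omega = 1 with transition bias: the estimator recovers neutrality
        on a long alignment."""
        aln, _ = generate_codon_alignment(
            AlignmentSpec(n_taxa=6, n_codons=800, omega=1.0, seed=13))
        res = gene_kaks(aln)
        assert 0.8 < res.ratio < 1.25

    @pytest.mark.parametrize(
        "field,value", [("omega", 0.0), ("n_codons", 5), ("n_taxa", 1)])
    def test_invalid_specs_rejected(self, field, value):
        spec = AlignmentSpec(**{field: value})
        with pytest.raises(ComputeError):
            spec.validate()


def test_published_layout_is_internally_consistent():
    """The default layout telescopes to the declared circle length."""
    spans = sum(
        (f.end - f.start + 1) if f.start <= f.end
        else (16592 - f.start + 1) + f.end
        for f in RECTORIS_LAYOUT
    )
    gaps = 0
    for i, f in enumerate(RECTORIS_LAYOUT):
        nxt = RECTORIS_LAYOUT[(i + 1) % len(RECTORIS_LAYOUT)]
        next_start = nxt.start + (16592 if i + 1 == len(RECTORIS_LAYOUT) else 0)
        gaps += next_start - f.end - 1
    assert spans + gaps == 16592
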