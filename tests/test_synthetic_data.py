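"""Unit and property tests for the synthetic-data generators."""

import dataclasses
import math

import numpy as np
import pytest

from crisprcolony import synthetic_data as sd
from crisprcolony import spacer_mapper as sm
from crisprcolony import timeshift as ts
from crisprcolony.array_parser import BarcodeSpec, RepeatModel, parse_reads, profile_colony
from crisprcolony.dna import gc_fraction


class TestConfig:
    def test_probability_bounds(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(priming_prob=1.5)
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(gc_content=-0.1)

    def test_genome_vs_spacer_length(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(genome_length=50, spacer_length=30)

    def test_repeat_distinct_from_leader(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(repeat_seq="ACGT", leader_seq="ACGT")


class TestGenerateGenome:
    def test_length_contract(self):
        cfg = sd.GeneratorConfig(genome_length=10_000, rng_seed=1)
        assert len(sd.generate_phage_genome(cfg)) == 10_000

    def test_determinism(self):
        cfg = sd.GeneratorConfig(genome_length=10_000, rng_seed=1)
        assert sd.generate_phage_genome(cfg) == sd.generate_phage_genome(cfg)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(genome_length=0)

    def test_gc_binomial_oracle(self):
        # per-base GC is an independent Bernoulli(gc): 3-SE binomial band
        cfg = sd.GeneratorConfig(genome_length=100_000, gc_content=0.5, rng_seed=7)
        g = sd.generate_phage_genome(cfg)
        se = math.sqrt(0.5 * 0.5 / 100_000)
        assert abs(gc_fraction(g) - 0.5) < 3 * se

    def test_alphabet(self):
        cfg = sd.GeneratorConfig(genome_length=2_000, rng_seed=3)
        assert set(sd.generate_phage_genome(cfg)) <= set("ACGT")


class TestSimulateColony:
    def test_priming_prob_zero_gives_single_spacer_arrays(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=0.0)
        colony = sd.simulate_colony(genome, plus_starts[0], 50, cfg)
        assert all(a.n_spacers == 1 for a in colony.arrays)

    def test_forced_local_mixture(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=1.0, local_fraction=1.0, local_window=500)
        colony = sd.simulate_colony(genome, plus_starts[10], 200, cfg)
        for labels in colony.truth_labels:
            for t in labels:
                if t.primed:
                    assert abs(t.position - plus_starts[10]) <= 500

    def test_multi_fraction_closed_form(self, genome, plus_starts, config):
        # P(>=2 spacers) = priming_prob under the geometric stopping rule
        p = 0.3
        cfg = dataclasses.replace(config, priming_prob=p)
        colony = sd.simulate_colony(genome, plus_starts[0], 10_000, cfg)
        frac = sum(a.n_spacers >= 2 for a in colony.arrays) / 10_000
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) < 3 * se

    def test_array_cap(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=1.0)
        colony = sd.simulate_colony(genome, plus_starts[0], 100, cfg)
        assert all(a.n_spacers == sd.MAX_ARRAY_SIZE for a in colony.arrays)

    def test_invalid_founder_position_rejected(self, genome, config):
        starts = {s for s, st in sd.valid_protospacer_starts(genome, config.spacer_length)
                  if st == "+"}
        bad = next(i for i in range(len(genome)) if i not in starts)
        with pytest.raises(sd.InvalidTargetError):
            sd.simulate_colony(genome, bad, 5, config)

    def test_founder_is_leader_distal_and_barcode_shared(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=0.8)
        colony = sd.simulate_colony(genome, plus_starts[3], 100, cfg)
        for a in colony.arrays:
            assert a.spacers[-1] == colony.founder_spacer
            assert a.barcode == colony.barcode
            assert a.n_spacers >= 1


class TestSimulateReads:
    def test_error_free_single_spacer_read_structure(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=0.0, read_error_rate=0.0)
        colony = sd.simulate_colony(genome, plus_starts[0], 1, cfg)
        [(_, seq)] = sd.simulate_reads(colony, cfg)
        assert seq.count(cfg.repeat_seq) == 2

    def test_round_trip_through_parser(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=0.5, read_error_rate=0.0)
        colony = sd.simulate_colony(genome, plus_starts[7], 50, cfg)
        reads = sd.simulate_reads(colony, cfg)
        model = RepeatModel(cfg.repeat_seq, max_mismatches=0)
        spec = BarcodeSpec(cfg.barcode_length, len(cfg.leader_seq))
        result = parse_reads(reads, model, barcode_spec=spec)
        assert result.n_unparseable == 0 and result.n_malformed == 0
        for parsed, truth in zip(result.arrays, colony.arrays):
            assert parsed.spacers == truth.spacers
            assert parsed.barcode == truth.barcode

    def test_order_preserved_for_three_spacer_array(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=1.0, read_error_rate=0.0)
        rng = np.random.default_rng(5)
        colony = sd.simulate_colony(genome, plus_starts[2], 30, cfg, rng=rng)
        three = next(a for a in colony.arrays if a.n_spacers >= 3)
        colony.arrays = [three]
        [(_, seq)] = sd.simulate_reads(colony, cfg, rng=rng)
        model = RepeatModel(cfg.repeat_seq, max_mismatches=0)
        from crisprcolony.array_parser import extract_array

        assert extract_array(seq, model).spacers == three.spacers

    def test_read_conservation_vs_profile(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=0.4, read_error_rate=0.0)
        colony = sd.simulate_colony(genome, plus_starts[1], 200, cfg)
        reads = sd.simulate_reads(colony, cfg, reads_per_array=2)
        result = parse_reads(reads, RepeatModel(cfg.repeat_seq, max_mismatches=0))
        profile = profile_colony(result.arrays)
        assert profile.n_reads == len(reads)

    def test_seeded_determinism_byte_identical(self, genome, plus_starts, config):
        cfg = dataclasses.replace(config, priming_prob=0.3, read_error_rate=0.01, rng_seed=42)
        out = []
        for _ in range(2):
            rng = cfg.rng()
            colony = sd.simulate_colony(genome, plus_starts[4], 40, cfg, rng=rng)
            out.append(sd.simulate_reads(colony, cfg, rng=rng))
        assert out[0] == out[1]


class TestEscaperPopulation:
    def test_zero_freq_all_wild_type(self, genome, plus_starts, config):
        spacer = genome[plus_starts[0]: plus_starts[0] + config.spacer_length]
        pop = sd.simulate_escaper_population(genome, spacer, 0.0, "seed", 10_000, seed=1)
        assert len(pop.variants) == 1
        assert pop.variants[0].label == "wild-type"
        assert pop.total == 10_000

    def test_expected_escaper_count_poisson(self, genome, plus_starts, config):
        # mean 1e-5 * 2e9 = 20,000; a seeded draw must land within 5 SD
        spacer = genome[plus_starts[0]: plus_starts[0] + config.spacer_length]
        pop = sd.simulate_escaper_population(
            genome, spacer, 1e-5, "seed", 2_000_000_000, seed=8
        )
        n_esc = pop.variants[1].count
        assert abs(n_esc - 20_000) < 5 * math.sqrt(20_000)
        assert pop.total == 2_000_000_000

    @pytest.mark.parametrize("mutation_class", ["seed", "PAM"])
    def test_classification_closed_loop(self, genome, plus_starts, config, mutation_class):
        start = plus_starts[20]
        spacer = genome[start: start + config.spacer_length]
        pop = sd.simulate_escaper_population(
            genome, spacer, 0.5, mutation_class, 1_000, seed=9
        )
        escaper = next(v for v in pop.variants if v.label == "escaper")
        hit = sm.map_spacer(spacer, genome)
        wild = sm.extract_target(genome, hit)
        mut_hit = sm.ProtospacerHit(
            spacer=spacer, start=hit.start, strand=hit.strand, pam="", mismatches=0
        )
        mutant = sm.extract_target(escaper.genome, mut_hit)
        assert sm.classify_escape_mutation(wild, mutant).category == mutation_class

    def test_escaper_escapes_and_wild_type_is_targeted(self, genome, plus_starts, config):
        start = plus_starts[30]
        spacer = genome[start: start + config.spacer_length]
        pop = sd.simulate_escaper_population(genome, spacer, 0.5, "seed", 1_000, seed=10)
        escaper = next(v for v in pop.variants if v.label == "escaper")
        assert sm.map_spacer(spacer, genome, max_mismatches=0) is not None
        assert sm.map_spacer(spacer, escaper.genome, max_mismatches=0) is None

    def test_absent_protospacer_rejected(self, genome):
        with pytest.raises(sd.InvalidTargetError):
            sd.simulate_escaper_population(genome, "A" * 30, 0.1, "seed", 100, seed=1)

    def test_bad_mutation_class(self, genome, plus_starts, config):
        spacer = genome[plus_starts[0]: plus_starts[0] + config.spacer_length]
        with pytest.raises(ValueError):
            sd.simulate_escaper_population(genome, spacer, 0.1, "distal", 100, seed=1)


class TestPlaqueAssay:
    def test_no_spacer_host_counts_scale_with_dilution(self, genome):
        pop = sd.PhagePopulation(
            variants=(sd.PhageVariant(genome=genome, count=1_000_000, label="wild-type"),)
        )
        assay = sd.simulate_plaque_assay(pop, [], [1e-3], seed=1)
        [(d, count)] = assay.spot_counts
        mean = 1_000_000 * 1e-3
        assert abs(count - mean) < 5 * math.sqrt(mean)

    def test_escaper_frequency_sets_plaque_mean(self, genome, plus_starts, config):
        # ~100 escapers of 1e9 phage at freq 1e-7: undiluted mean 100
        start = plus_starts[40]
        spacer = genome[start: start + config.spacer_length]
        pop = sd.simulate_escaper_population(genome, spacer, 1e-7, "seed", 1_000_000_000, seed=3)
        assay = sd.simulate_plaque_assay(pop, [spacer], [1.0], seed=4)
        [(_, count)] = assay.spot_counts
        assert 40 < count < 160  # Poisson(~100), 5+ SD band

    def test_triple_spacer_host_below_detection(self, genome, plus_starts, config):
        start = plus_starts[50]
        founder = genome[start: start + config.spacer_length]
        others = [genome[p: p + config.spacer_length] for p in (plus_starts[80], plus_starts[120])]
        pop = sd.simulate_escaper_population(genome, founder, 1e-6, "seed", 1_000_000_000, seed=5)
        assay = sd.simulate_plaque_assay(pop, [founder] + others, [1.0, 0.1], seed=6)
        assert all(c == 0 for _, c in assay.spot_counts)
        from crisprcolony.escape_assay import titer

        assert titer(assay).below_detection

    def test_dilution_factor_validation(self, genome):
        pop = sd.PhagePopulation(variants=(sd.PhageVariant(genome, 10, "wild-type"),))
        with pytest.raises(ValueError):
            sd.simulate_plaque_assay(pop, [], [0.0], seed=1)


class TestSimulateTimeshift:
    def test_none_rule_all_identical(self):
        m = sd.simulate_timeshift(4, [24, 36, 48], "none", seed=1)
        assert len(np.unique(m.scores)) == 1

    def test_monotone_rule_contemporary_non_decreasing(self):
        m = sd.simulate_timeshift(6, [24, 36, 48], "monotone", seed=2)
        by_tp = {}
        for t in ts.trajectories(m):
            if t.contemporary_score is not None:
                by_tp.setdefault(t.host_timepoint, []).append(t.contemporary_score)
        tps = sorted(by_tp)
        means = [np.mean(by_tp[tp]) for tp in tps]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_design_shape(self):
        # 12 colonies at each of three time points, 12 phages per time point
        m = sd.simulate_timeshift(12, [24, 36, 48], "monotone", seed=3)
        assert sum(tp == 24 for _, tp in m.hosts) == 12
        assert sum(tp == 0 for _, tp in m.phages) == 12
        assert m.scores.shape == (1 + 36, 48)

    def test_scores_are_ordinal(self):
        m = sd.simulate_timeshift(5, [24, 48], "monotone", seed=4, noise=1.0)
        assert set(np.unique(m.scores)) <= {0.0, 0.5, 1.0}

    def test_unordered_timepoints_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_timeshift(3, [48, 24], "monotone", seed=1)
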