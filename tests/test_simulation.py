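from __future__ import annotations

import math

import pytest

from mdm import (
    count_kmers,
    estimate_trinucleotide,
    generate_genome,
    oracle_check,
    simulate_cpg_decay,
)
from mdm.simulation import SimConfig


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        config = SimConfig(length=5_000, gc=50.0, seed=42)
        assert generate_genome(config).seq == generate_genome(config).seq

    def test_gc_100_is_all_cg(self):
        genome = generate_genome(SimConfig(length=1_000, gc=100.0, seed=1))
        assert set(genome.seq) <= {"C", "G"}

    def test_dinucleotide_proportions_near_product_form(self):
        n = 100_000
        genome = generate_genome(SimConfig(length=n, gc=50.0, seed=8))
        di = count_kmers(genome, 2)
        sigma = math.sqrt(0.0625 * (1 - 0.0625) / di.total)
        for d, c in di.counts.items():
            assert abs(c / di.total - 0.0625) < 4 * sigma, d

    def test_cgi_blocks_inserted(self):
        config = SimConfig(length=30_000, gc=40.0, seed=4, cgi_blocks=((400, 10_000),))
        genome = generate_genome(config)
        assert genome.seq[10_000 : 10_400] == "CG" * 200

    @pytest.mark.parametrize("length, gc", [(1, 50.0), (100, 0.0), (100, 101.0)])
    def test_invalid_config_rejected(self, length, gc):
        with pytest.raises(ValueError):
            SimConfig(length=length, gc=gc)


class TestSimulateDecay:
    def test_forced_tpg_branch_single_site(self, contig):
        after, events = simulate_cpg_decay(contig("ACGT"), 1, seed=0, p_tpg=1.0)
        assert after.seq == "ATGT"
        assert events[0].outcome == "TpG"

    def test_forced_cpa_branch_single_site(self, contig):
        after, events = simulate_cpg_decay(contig("ACGT"), 1, seed=0, p_tpg=0.0)
        assert after.seq == "ACAT"
        assert events[0].outcome == "CpA"

    def test_zero_events_identity(self, contig):
        c = contig("ACGTACGT")
        after, events = simulate_cpg_decay(c, 0, seed=0)
        assert after.seq == c.seq and events == []

    def test_too_many_events_reports_remaining(self, contig):
        with pytest.raises(ValueError, match="2 CpG sites"):
            simulate_cpg_decay(contig("ACGTACGT"), 5, seed=0)

    def test_large_decay_counts_and_branch_balance(self):
        genome = generate_genome(SimConfig(length=200_000, gc=50.0, seed=12))
        n_events = 2_000
        after, events = simulate_cpg_decay(genome, n_events, seed=12)
        assert len(after.seq) == len(genome.seq)
        assert genome.seq.count("CG") - after.seq.count("CG") == n_events
        n_tpg = sum(1 for e in events if e.outcome == "TpG")
        assert abs(n_tpg - n_events / 2) < 4 * math.sqrt(n_events * 0.25)

    def test_each_event_changes_exactly_one_letter(self):
        genome = generate_genome(SimConfig(length=10_000, gc=50.0, seed=2))
        n_events = 50
        after, _ = simulate_cpg_decay(genome, n_events, seed=2)
        changed = sum(a != b for a, b in zip(genome.seq, after.seq))
        assert changed == n_events

    def test_dinucleotide_total_conserved(self):
        genome = generate_genome(SimConfig(length=10_000, gc=50.0, seed=2))
        after, _ = simulate_cpg_decay(genome, 100, seed=2)
        assert count_kmers(after, 2).total == count_kmers(genome, 2).total


class TestOracle:
    def test_model_matches_simulation_in_sparse_regime(self):
        """The change matrix Q predicts the forward simulation: every
        dinucleotide's empirical count change on a 200 kb genome with
        2000 events lies within 4 sigma of the prediction."""
        genome = genome_200kb()
        params = estimate_trinucleotide(count_kmers(genome, 3))
        after, _ = simulate_cpg_decay(genome, 2_000, seed=77)
        z = oracle_check(genome, after, params, 2_000)
        for d, zd in z.items():
            assert abs(zd) < 4.0, (d, zd)

    def test_tpa_untouched(self):
        genome = genome_200kb()
        params = estimate_trinucleotide(count_kmers(genome, 3))
        after, _ = simulate_cpg_decay(genome, 2_000, seed=78)
        before_ta = count_kmers(genome, 2)["TA"]
        after_ta = count_kmers(after, 2)["TA"]
        assert before_ta == after_ta
        assert oracle_check(genome, after, params, 2_000)["TA"] == 0.0

    def test_zero_events_zero_scores(self):
        genome = generate_genome(SimConfig(length=5_000, gc=50.0, seed=6))
        params = estimate_trinucleotide(count_kmers(genome, 3))
        z = oracle_check(genome, genome, params, 0)
        assert all(v == 0.0 for v in z.values())


def genome_200kb():
    return generate_genome(SimConfig(length=200_000, gc=50.0, seed=77))


class TestParameterRecovery:
    def test_error_shrinks_at_root_l_rate(self):
        """Trinucleotide estimates converge to the generator's uniform
        flank distribution; the multinomial bound holds at both lengths
        and the longer genome estimates better."""
        errors = {}
        for length in (20_000, 320_000):
            genome = generate_genome(SimConfig(length=length, gc=50.0, seed=31))
            params = estimate_trinucleotide(count_kmers(genome, 3))
            n_cpg = genome.seq.count("CG")
            sigma = math.sqrt(0.25 * 0.75 / n_cpg)
            errs = [abs(v - 0.25) for v in params.p + params.pp]
            assert max(errs) < 4 * sigma
            errors[length] = max(errs)
        assert errors[320_000] < errors[20_000]
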