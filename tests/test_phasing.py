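import io
import itertools

import numpy as np
import pytest

from oracles import oracle_block_errors
from scaffcheck.phasing import (
    HetSite,
    PhasedBlock,
    PhasedSite,
    TruthPhase,
    block_stats,
    depth_filter,
    evaluate_phase,
    join_switch_fraction,
    polarize_from_truth,
    polarize_paf,
    read_paf,
    read_phased_vcf,
)
from scaffcheck.synthetic import (
    SimConfig,
    phasing_benchmark,
    simulate_f1,
    simulate_phased_blocks,
    write_phased_vcf,
)


def make_block(disagreement, block_id="b", start=100, step=10):
    """Block + truth realizing a given 0/1 disagreement pattern."""
    truth = {}
    sites = []
    for k, d in enumerate(disagreement):
        pos = start + k * step
        truth[("chr1", pos)] = ("A", "C")
        h0, h1 = ("A", "C") if d == 0 else ("C", "A")
        sites.append(PhasedSite("chr1", pos, h0, h1))
    return PhasedBlock(block_id, sites), TruthPhase(truth)


class TestDepthFilter:
    def test_decile_convention(self):
        sites = [HetSite("c", i, ("A", "C"), depth=i) for i in range(1, 11)]
        kept = depth_filter(sites)
        assert [s.depth for s in kept] == list(range(2, 10))

    def test_equal_depths_all_retained(self):
        sites = [HetSite("c", i, ("A", "C"), depth=30) for i in range(20)]
        assert len(depth_filter(sites)) == 20

    def test_matches_independent_percentile(self):
        rng = np.random.default_rng(8)
        depths = rng.integers(0, 100, size=1000)
        sites = [HetSite("c", i, ("A", "C"), depth=int(d)) for i, d in enumerate(depths)]
        kept = depth_filter(sites)
        lo = np.percentile(depths, 10)
        hi = np.percentile(depths, 90)
        expected = int(np.sum((depths >= lo) & (depths <= hi)))
        assert len(kept) == expected
        assert 700 < len(kept) < 900


class TestPolarize:
    def test_truth_table_path_is_exact(self):
        """Synthetic F1: every polarized label equals the construction truth."""
        seq_a, seq_b, truth = simulate_f1(SimConfig(seed=2, genome_length=100_000, theta=0.01))
        sites = [
            HetSite(ref, pos, alleles, depth=30)
            for (ref, pos), alleles in truth.items()
        ]
        polarized, diag = polarize_from_truth(sites, truth)
        assert diag["polarized"] == len(sites) > 0
        assert diag["inconsistent"] == 0
        for (ref, pos), (a, b) in polarized.items():
            assert seq_a[pos] == a and seq_b[pos] == b

    def test_unknown_site_left_unpolarized(self):
        truth = TruthPhase({("c", 5): ("A", "C")})
        sites = [HetSite("c", 99, ("A", "C"))]
        polarized, diag = polarize_from_truth(sites, truth)
        assert len(polarized) == 0 and diag["unpolarized"] == 1

    def test_paf_polarization(self):
        # parent aligns to assembly target positions [0,20); substitution at
        # target pos 5 (assembly G, parent T); deletion of target pos 10.
        paf = (
            "parent\t30\t0\t20\t+\tasm\t40\t0\t20\t18\t20\t60\t"
            "cs:Z::5*gt:4-a:9\n"
        )
        alignments = read_paf(paf)
        sites = [
            HetSite("asm", 2, ("A", "C")),    # identity region: REF is parental
            HetSite("asm", 5, ("G", "T")),    # parent carries ALT
            HetSite("asm", 5 + 30, ("A", "C")),  # outside alignment
        ]
        truth, diag = polarize_paf(sites, alignments)
        assert truth.get("asm", 2) == ("A", "C")
        assert truth.get("asm", 5) == ("T", "G")
        assert diag["unpolarized"] == 1

    def test_paf_inconsistent_site_tallied(self):
        paf = "p\t30\t0\t10\t+\tasm\t40\t0\t10\t9\t10\t60\tcs:Z::4*ga:5\n"
        sites = [HetSite("asm", 4, ("G", "C"))]  # parent base A matches neither
        truth, diag = polarize_paf(sites, read_paf(paf))
        assert len(truth) == 0 and diag["inconsistent"] == 1


class TestEvaluatePhase:
    def test_perfect_block(self):
        block, truth = make_block([0, 0, 0, 0, 0])
        rep = evaluate_phase([block], truth)
        assert (rep.n_switch, rep.n_mismatch) == (0, 0)
        assert rep.combined_rate == 0.0

    def test_single_flip_is_mismatch(self):
        """A lone mis-phased variant in an otherwise correct block."""
        block, truth = make_block([0, 0, 1, 0, 0])
        rep = evaluate_phase([block], truth)
        assert (rep.n_switch, rep.n_mismatch) == (0, 1)

    def test_terminal_run_is_one_switch(self):
        """>=2 consecutive wrong variants after correct ones: one change-point."""
        block, truth = make_block([0, 0, 0, 1, 1, 1])
        rep = evaluate_phase([block], truth)
        assert (rep.n_switch, rep.n_mismatch) == (1, 0)

    def test_interior_run_counts_both_change_points(self):
        block, truth = make_block([0, 0, 0, 1, 1, 0, 0, 0])
        rep = evaluate_phase([block], truth)
        assert (rep.n_switch, rep.n_mismatch) == (2, 0)

    def test_orientation_symmetry(self):
        pattern = [0, 1, 1, 0, 1, 0, 0, 1]
        block, truth = make_block(pattern)
        flipped, _ = make_block([1 - d for d in pattern])
        a = evaluate_phase([block], truth)
        b = evaluate_phase([flipped], truth)
        assert (a.n_switch, a.n_mismatch) == (b.n_switch, b.n_mismatch)

    def test_combined_rate_identity(self):
        block, truth = make_block([0, 1, 0, 1, 1, 0, 0, 1, 1, 1])
        rep = evaluate_phase([block], truth)
        assert rep.combined_rate * rep.n_sites == rep.n_switch + rep.n_mismatch

    def test_single_site_blocks_contribute_no_errors(self):
        block, truth = make_block([1], block_id="lonely")
        rep = evaluate_phase([block], truth)
        assert rep.n_sites == 1 and rep.n_switch == 0 and rep.n_mismatch == 0

    def test_unlabeled_sites_excluded_and_tallied(self):
        block, truth = make_block([0, 0, 0])
        block.sites.append(PhasedSite("chr1", 999, "A", "C"))
        rep = evaluate_phase([block], truth)
        assert rep.n_excluded == 1 and rep.n_sites == 3

    @pytest.mark.parametrize("n", range(2, 10))
    def test_matches_enumeration_oracle(self, n):
        """All 2^n disagreement patterns agree with the brute-force
        orientation-enumeration oracle (full n<=12 sweep in acceptance)."""
        for pattern in itertools.product((0, 1), repeat=n):
            block, truth = make_block(pattern)
            rep = evaluate_phase([block], truth)
            assert (rep.n_switch, rep.n_mismatch) == oracle_block_errors(pattern)

    def test_recovers_planted_switch_rate(self):
        blocks, truth, bundle = phasing_benchmark(50_000, 200, 0.0126, 0.0, seed=3)
        rep = evaluate_phase(blocks, truth)
        planted = len(bundle.switch_adjacencies) / rep.n_sites
        se = np.sqrt(0.0126 * (1 - 0.0126) / rep.n_sites)
        assert abs(rep.switch_rate - planted) <= 3 * se
        assert abs(rep.switch_rate - 0.0126) <= 3 * se


class TestBlockStats:
    def test_single_block(self):
        block, _ = make_block([0] * 5)
        stats = block_stats([block])
        assert stats["mean_block_len"] == 5
        assert stats["largest_block_fraction"] == 1.0

    def test_two_blocks(self):
        b1, _ = make_block([0] * 4, block_id="b1")
        b2, _ = make_block([0] * 6, block_id="b2", start=10_000)
        stats = block_stats([b1, b2])
        assert stats["mean_block_len"] == 5
        assert stats["largest_block_fraction"] == pytest.approx(0.6)

    def test_span(self):
        block, _ = make_block([0, 0, 0], start=100, step=50)
        assert block_stats([block])["mean_block_span"] == 100


class TestJoinSwitchFraction:
    def test_reported_regime(self):
        """Per-site switch increase x mean block length, truncated to a
        whole percent, matches the ~17% block-join failure estimate."""
        frac = join_switch_fraction(0.0126, 14)
        assert frac == pytest.approx(0.1764)
        assert int(frac * 100) == 17

    def test_zero_rate(self):
        assert join_switch_fraction(0.0, 1000) == 0.0

    def test_arithmetic(self):
        assert join_switch_fraction(0.05, 10) == pytest.approx(0.5)


class TestVcfRoundTrip:
    def test_blocks_survive_vcf(self, tmp_path):
        blocks, truth, _ = phasing_benchmark(400, 20, 0.05, 0.01, seed=6)
        path = tmp_path / "phased.vcf"
        with open(path, "w") as fh:
            write_phased_vcf(blocks, truth, fh)
        blocks2, sites = read_phased_vcf(str(path))
        direct = evaluate_phase(blocks, truth)
        via_vcf = evaluate_phase(blocks2, truth)
        assert via_vcf.n_sites == direct.n_sites == 400
        assert (via_vcf.n_switch, via_vcf.n_mismatch) == (direct.n_switch, direct.n_mismatch)
        assert all(s.depth == 30 for s in sites)
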