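import numpy as np
import pytest

from oracles import naive_spanning_count
from scaffcheck.assembly import Breakpoint, ContigSpan, Scaffold, ScaffoldLayout
from scaffcheck.misjoin import (
    InsulationResult,
    MisjoinParams,
    call_misjoins,
    false_join_null,
    scan_joins,
    spanning_count,
)
from scaffcheck.pairs import ContactSet
from scaffcheck.synthetic import SimConfig, misjoin_benchmark, simulate_contacts

REFS = {"s": 10_000}


def _pairs(records, refs=REFS):
    return ContactSet.from_records(records, refs)


class TestSpanningCount:
    def test_empty_set(self):
        assert spanning_count(_pairs([]), "s", 5000, 1000) == 0

    def test_straddling_pair(self):
        cs = _pairs([("s", 4990, "+", "s", 5010, "-")])
        assert spanning_count(cs, "s", 5000, 1000) == 1

    def test_far_end_at_window_bound_excluded(self):
        cs = _pairs([("s", 4990, "+", "s", 6000, "-")])
        assert spanning_count(cs, "s", 5000, 1000) == 0
        # near bound is inclusive
        cs2 = _pairs([("s", 4000, "+", "s", 5000, "-")])
        assert spanning_count(cs2, "s", 5000, 1000) == 1

    def test_monotone_in_window(self):
        rng = np.random.default_rng(0)
        recs = [
            ("s", int(a), "+", "s", int(b), "-")
            for a, b in rng.integers(0, 10_000, size=(300, 2))
        ]
        cs = _pairs(recs)
        scores = [spanning_count(cs, "s", 5000, w) for w in (10, 100, 1000, 5000, 10_000)]
        assert scores == sorted(scores)

    def test_matches_naive_scan(self):
        rng = np.random.default_rng(1)
        refs = {"s": 10_000, "t": 8_000}
        recs = []
        for _ in range(500):
            r1, r2 = rng.choice(["s", "t"], size=2)
            recs.append(
                (r1, int(rng.integers(refs[r1])), "+", r2, int(rng.integers(refs[r2])), "-")
            )
        cs = _pairs(recs, refs)
        for pos in (100, 2500, 5000, 9_900):
            for w in (500, 3000):
                assert spanning_count(cs, "s", pos, w) == naive_spanning_count(cs, "s", pos, w)


class TestScanJoins:
    def test_two_contig_scaffold_has_one_junction(self):
        layout = ScaffoldLayout(
            [Scaffold("s", [ContigSpan("a", 0, 4000, "+"), ContigSpan("b", 0, 6000, "+")])]
        )
        res = scan_joins(_pairs([]), layout, MisjoinParams(window=1000))
        assert len(res) == 1
        assert (res[0].scaffold, res[0].position) == ("s", 4000)

    def test_single_contig_scaffolds_have_none(self):
        layout = ScaffoldLayout(
            [Scaffold(f"s{i}", [ContigSpan(f"c{i}", 0, 1000, "+")]) for i in range(5)]
        )
        refs = layout.reference_lengths()
        assert scan_joins(_pairs([], refs), layout, MisjoinParams(window=100)) == []

    def test_junction_score_equals_enumeration(self):
        """Junction score on decay-simulated contacts equals the direct
        enumeration oracle over the simulated pairs."""
        refs = {"s": 50_000}
        cfg = SimConfig(seed=2, n_contacts=2_000, trans_rate=0.0, dup_rate=0.0,
                        min_separation=100)
        contacts, _ = simulate_contacts(refs, cfg)
        layout = ScaffoldLayout(
            [Scaffold("s", [ContigSpan("a", 0, 25_000, "+"), ContigSpan("b", 0, 25_000, "+")])]
        )
        (res,) = scan_joins(contacts, layout, MisjoinParams(window=10_000))
        assert res.score == naive_spanning_count(contacts, "s", 25_000, 10_000)
        assert res.score > 0


def _unlinked_layout():
    return ScaffoldLayout(
        [
            Scaffold("sa", [ContigSpan("a", 0, 5000, "+")]),
            Scaffold("sb", [ContigSpan("b", 0, 5000, "+")]),
            Scaffold("sc", [ContigSpan("c", 0, 5000, "+")]),
        ]
    )


class TestFalseJoinNull:
    def test_no_trans_contacts_gives_zero_scores(self):
        layout = _unlinked_layout()
        refs = layout.reference_lengths()
        recs = [("sa", 10, "+", "sa", 400, "-")] * 5
        null = false_join_null(_pairs(recs, refs), layout, MisjoinParams(window=1000, seed=1))
        assert (null == 0).all()

    def test_sample_size(self):
        layout = _unlinked_layout()
        refs = layout.reference_lengths()
        null = false_join_null(_pairs([], refs), layout,
                               MisjoinParams(window=1000, n_null=100, seed=1))
        assert len(null) == 100

    def test_deterministic_under_seed(self):
        layout = _unlinked_layout()
        refs = layout.reference_lengths()
        rng = np.random.default_rng(3)
        recs = []
        for _ in range(400):
            r1, r2 = rng.choice(["sa", "sb", "sc"], size=2)
            recs.append((r1, int(rng.integers(5000)), "+", r2, int(rng.integers(5000)), "-"))
        cs = _pairs(recs, refs)
        p = MisjoinParams(window=2000, seed=42)
        assert np.array_equal(false_join_null(cs, layout, p), false_join_null(cs, layout, p))

    def test_requires_unlinked_contigs(self):
        layout = ScaffoldLayout(
            [Scaffold("s", [ContigSpan("a", 0, 100, "+"), ContigSpan("b", 0, 100, "+")])]
        )
        with pytest.raises(ValueError, match="unlinked"):
            false_join_null(_pairs([], layout.reference_lengths()), layout, MisjoinParams())

    def test_null_mean_matches_enumeration(self):
        """Uniform trans contacts: sampled null mean within 3 SD of the
        expectation enumerated over every unlinked geometry."""
        layout = _unlinked_layout()
        refs = layout.reference_lengths()
        rng = np.random.default_rng(7)
        names = ["sa", "sb", "sc"]
        recs = []
        for _ in range(600):
            i, j = rng.choice(3, size=2, replace=False)
            recs.append(
                (names[i], int(rng.integers(5000)), "+", names[j], int(rng.integers(5000)), "-")
            )
        cs = _pairs(recs, refs)
        W = 2000
        # enumeration oracle: score every ordered geometry by naive counting
        geom_scores = []
        for a in names:
            for b in names:
                if a == b:
                    continue
                n = 0
                for p in cs:
                    ends = [(p.ref1, p.pos1), (p.ref2, p.pos2)]
                    for (ra, pa), (rb, pb) in (tuple(ends), tuple(reversed(ends))):
                        if ra == a and pa >= 5000 - W and rb == b and pb < W:
                            n += 1
                            break
                geom_scores.append(n)
        expectation = np.mean(geom_scores)
        null = false_join_null(cs, layout, MisjoinParams(window=W, n_null=1000, seed=9))
        sd_mean = np.std(geom_scores) / np.sqrt(len(null))
        assert set(null) <= set(geom_scores)
        assert abs(null.mean() - expectation) <= 3 * sd_mean + 1e-9


class TestCallMisjoins:
    def _result(self, score):
        return InsulationResult("s", 100, score)

    def test_above_null_max_not_flagged(self):
        null = np.array([1, 2, 3, 4, 5])
        res = [self._result(6)]
        assert call_misjoins(res, null, MisjoinParams()) == []
        assert not res[0].flagged

    def test_null_median_flagged(self):
        null = np.arange(101)
        res = [self._result(50)]
        bps = call_misjoins(res, null, MisjoinParams(flag_quantile=0.95))
        assert bps == [Breakpoint("s", 100)]
        assert res[0].null_quantile == pytest.approx(51 / 101)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            call_misjoins([self._result(1)], np.array([]), MisjoinParams())

    def test_flagged_sorted_by_score(self):
        null = np.arange(101)
        res = [self._result(40), InsulationResult("t", 5, 10)]
        bps = call_misjoins(res, null, MisjoinParams())
        assert [bp.scaffold for bp in bps] == ["t", "s"]


class TestEndToEnd:
    def test_planted_misjoin_flagged_control_clean(self):
        """Desk-scale planted-misjoin benchmark: the planted junction is
        flagged, the true junction in the control scaffold is not."""
        bench = misjoin_benchmark(
            seed=11, contig_length=300_000, pairs_per_contig=20_000,
            filler_length=100_000,
        )
        params = MisjoinParams(window=100_000, n_null=1000, flag_quantile=0.95, seed=11)
        results = scan_joins(bench.contacts, bench.layout, params)
        null = false_join_null(bench.contacts, bench.layout, params)
        calls = call_misjoins(results, null, params)
        assert calls == [bench.planted_junction]
        control = [r for r in results if r.scaffold == bench.control_junction.scaffold]
        assert control and not control[0].flagged
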