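"""Structural and truth properties of the interval/query simulator."""

import math

import pytest

from ivbench import (
    SimConfig,
    make_complex_queries,
    make_gap_queries,
    make_interval_queries,
    simulate_reference,
    subsample_queries,
    write_dataset,
)
from ivbench.simulate import GAP_CATEGORIES, OVERLAP_CATEGORIES

from conftest import brute_force_hits


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"intvlnums": 0},
            {"intvlnums": 5, "intvlsize_min": 0},
            {"intvlnums": 5, "intvlsize_min": 50, "intvlsize_max": 10},
            {"intvlnums": 5, "gapsize_min": 200, "gapsize_max": 100},
            {"intvlnums": 5, "chrom_capacity": 10**9},
            {"intvlnums": 5, "subsample_fractions": (0.5, 0.2, 1.0)},
            {"intvlnums": 5, "subsample_fractions": (0.5, 0.9)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    @pytest.mark.parametrize(
        "n,expect", [(1, 1), (10, 1), (99, 9), (100, 10), (250, 24), (100_000, 24)]
    )
    def test_chromosome_allocation_rule(self, n, expect):
        assert SimConfig(intvlnums=n).used_chromosomes() == expect


class TestReferenceStructure:
    def test_small_dataset_layout(self):
        """10 intervals land on chr1 with in-bounds lengths and a gap before
        every interval."""
        cfg = SimConfig(intvlnums=10, seed=1)
        ref = simulate_reference(cfg)
        assert ref.chrom_order == ["chr1"]
        ivs, gps = ref.intervals["chr1"], ref.gaps["chr1"]
        assert len(ivs) == 10 and len(gps) == 10
        cursor = 0
        for g, iv in zip(gps, ivs):
            assert g.start == cursor and g.end == iv.start  # gap,interval,gap,...
            assert cfg.gapsize_min <= g.length <= cfg.gapsize_max
            assert cfg.intvlsize_min <= iv.length <= cfg.intvlsize_max
            cursor = iv.end
        assert ref.tails["chr1"].start == ivs[-1].end

    def test_single_interval_degenerate(self):
        ref = simulate_reference(SimConfig(intvlnums=1, seed=7))
        assert len(ref) == 1 and ref.chrom_order == ["chr1"]
        assert len(ref.gaps["chr1"]) == 1

    def test_every_used_chromosome_meets_minimum(self):
        ref = simulate_reference(SimConfig(intvlnums=250, seed=2))
        assert len(ref.chrom_order) == 24
        assert all(len(ref.intervals[c]) >= 10 for c in ref.chrom_order)
        assert len(ref) == 250

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sorted_nonoverlapping_capacity(self, seed):
        ref = simulate_reference(SimConfig(intvlnums=500, seed=seed))
        for c in ref.chrom_order:
            ivs = ref.intervals[c]
            for a, b in zip(ivs, ivs[1:]):
                assert a.end < b.start  # non-adjacent: separated by a gap
            assert ref.tails[c].end <= 2_000_000_000

    def test_reproducibility(self):
        cfg = SimConfig(intvlnums=50, seed=11)
        r1, r2 = simulate_reference(cfg), simulate_reference(cfg)
        assert r1.all_intervals() == r2.all_intervals()
        assert r1.tails == r2.tails


class TestQueryTruth:
    """The simulator's central property: every emitted query carries truth
    that an exhaustive scan of the reference confirms exactly."""

    @pytest.mark.parametrize("n,seed", [(10, 1), (100, 2), (100, 9)])
    def test_overlap_queries_hit_exactly_their_target(self, n, seed):
        ref = simulate_reference(SimConfig(intvlnums=n, seed=seed))
        ivs = ref.all_intervals()
        qs = make_interval_queries(ref)
        assert len(qs) == 5 * n
        for q in qs:
            assert q.category in OVERLAP_CATEGORIES
            assert brute_force_hits(ivs, q.query) == list(q.expected_ids)

    @pytest.mark.parametrize("n,seed", [(10, 1), (100, 2), (100, 9)])
    def test_gap_queries_hit_nothing(self, n, seed):
        ref = simulate_reference(SimConfig(intvlnums=n, seed=seed))
        ivs = ref.all_intervals()
        qs = make_gap_queries(ref)
        assert len(qs) == 5 * n
        for q in qs:
            assert q.category in GAP_CATEGORIES
            assert q.expected_count == 0
            assert brute_force_hits(ivs, q.query) == []

    @pytest.mark.parametrize("n,seed", [(30, 4), (100, 2)])
    def test_complex_queries_count_exactly_k(self, n, seed):
        ref = simulate_reference(SimConfig(intvlnums=n, seed=seed))
        ivs = ref.all_intervals()
        for q in make_complex_queries(ref):
            assert len(brute_force_hits(ivs, q.query)) == q.expected_count

    def test_complex_per_chromosome_span_range(self):
        ref = simulate_reference(SimConfig(intvlnums=100, seed=2))
        qs = make_complex_queries(ref)
        per_chrom = {}
        for q in qs:
            per_chrom.setdefault(q.query.chrom, []).append(q.expected_count)
        for c, ks in per_chrom.items():
            n = len(ref.intervals[c])
            assert sorted(ks) == list(range(2, n + 1))  # one query per k

    def test_decile_bins(self):
        ref = simulate_reference(SimConfig(intvlnums=10, seed=1))
        qs = make_complex_queries(ref)
        n = 10
        for q in qs:
            assert q.decile_bin == min(10, max(1, math.ceil(10 * q.expected_count / n)))
        assert {q.decile_bin for q in qs if q.expected_count == 10} == {10}

    def test_ten_queries_per_reference_interval(self):
        ref = simulate_reference(SimConfig(intvlnums=100, seed=5))
        total = len(make_interval_queries(ref)) + len(make_gap_queries(ref))
        assert total == 10 * 100

    def test_query_feasibility_guards(self):
        ref = simulate_reference(SimConfig(intvlnums=5, seed=1))
        bad_gap = SimConfig(intvlnums=5, gapsize_min=2, gapsize_max=5, seed=1)
        with pytest.raises(ValueError):
            make_gap_queries(simulate_reference(bad_gap))
        bad_iv = SimConfig(intvlnums=5, intvlsize_min=2, intvlsize_max=2, seed=1)
        with pytest.raises(ValueError):
            make_interval_queries(simulate_reference(bad_iv))
        assert make_interval_queries(ref)  # defaults are feasible


class TestSubsampling:
    def test_sizes_and_nesting(self):
        ref = simulate_reference(SimConfig(intvlnums=20, seed=8))
        qs = make_interval_queries(ref)  # N = 100
        fam = subsample_queries(qs, seed=8)
        sizes = [len(fam[round(0.1 * i, 1)]) for i in range(1, 11)]
        assert sizes == [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
        ids = lambda f: {q.query.id for q in fam[f]}
        fr = sorted(fam)
        for a, b in zip(fr, fr[1:]):
            assert ids(a) <= ids(b)  # chain under inclusion
        assert fam[1.0] == list(qs)  # identity fraction, input order

    def test_rounding_half_up(self):
        ref = simulate_reference(SimConfig(intvlnums=10, seed=8))
        qs = make_interval_queries(ref)[:7]
        fam = subsample_queries(qs, fractions=(0.1, 1.0), seed=0)
        assert len(fam[0.1]) == 1  # round(0.7) -> 1

    def test_empty_input(self):
        fam = subsample_queries([], fractions=(0.5, 1.0), seed=0)
        assert all(v == [] for v in fam.values())


class TestDatasetEmission:
    def test_written_dataset_is_deterministic(self, tmp_path):
        cfg = SimConfig(intvlnums=30, seed=13)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_reference(cfg), d1)
        write_dataset(simulate_reference(cfg), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_expected_files_present(self, dataset100):
        names = {p.name for p in dataset100.iterdir()}
        expect = {"ref.bed", "queries_basic.bed", "queries_gap.bed",
                  "queries_complex.bed", "truth.tsv"}
        expect |= {f"queries_basic.p{p}.bed" for p in range(10, 101, 10)}
        expect |= {f"queries_gap.p{p}.bed" for p in range(10, 101, 10)}
        assert expect <= names
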