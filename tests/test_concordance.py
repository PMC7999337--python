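"""Reciprocal-overlap matching and type-stratified concordance."""

import numpy as np
import pytest

from svconcord.concordance import (
    INTERVAL_TYPES,
    MatchConfig,
    match_callsets,
    match_translocations,
    reciprocal_overlap,
    translocation_match,
    type_composition,
)
from svconcord.io import GenomicInterval, SVCallset

from conftest import make_event, make_record, random_interval_callset


class TestReciprocalOverlap:
    def test_identity(self):
        a = GenomicInterval("1", 100, 200)
        assert reciprocal_overlap(a, a) == (1.0, 1.0)

    def test_half_overlap_fails_the_default_threshold(self):
        a = GenomicInterval("1", 100, 200)
        b = GenomicInterval("1", 150, 250)
        fa, fb = reciprocal_overlap(a, b)
        assert fa == fb == 0.5
        assert not (fa >= 0.70 and fb >= 0.70)

    def test_disjoint(self):
        a = GenomicInterval("1", 100, 200)
        b = GenomicInterval("1", 300, 400)
        assert reciprocal_overlap(a, b) == (0.0, 0.0)

    def test_different_chromosomes(self):
        a = GenomicInterval("1", 100, 200)
        b = GenomicInterval("2", 100, 200)
        assert reciprocal_overlap(a, b) == (0.0, 0.0)

    def test_symmetric_under_swap(self):
        a = GenomicInterval("1", 0, 1000)
        b = GenomicInterval("1", 500, 750)
        assert reciprocal_overlap(a, b) == tuple(reversed(reciprocal_overlap(b, a)))


def brute_force_table(a, b, cfg):
    """O(n^2) reference matcher (directional unique-feature semantics)."""
    def matches(x, y):
        if x.svtype != y.svtype:
            return False
        if x.svtype == "INS":
            return (x.interval.chrom == y.interval.chrom
                    and abs(x.interval.start - y.interval.start) <= cfg.ins_window)
        fa, fb = reciprocal_overlap(x.interval, y.interval)
        if cfg.reciprocal:
            return fa >= cfg.fraction and fb >= cfg.fraction
        return fa >= cfg.fraction

    out = {}
    for svtype in INTERVAL_TYPES:
        ra = a.interval_records(svtype)
        rb = b.interval_records(svtype)
        shared = sum(1 for x in ra if any(matches(x, y) for y in rb))
        shared_b = sum(1 for y in rb if any(matches(x, y) for x in ra))
        out[svtype] = {"n_a": len(ra), "n_b": len(rb), "shared": shared,
                       "a_only": len(ra) - shared, "b_only": len(rb) - shared_b,
                       "shared_b": shared_b}
    return out


class TestMatchCallsets:
    def test_self_comparison_has_no_a_only(self):
        rng = np.random.default_rng(0)
        a = random_interval_callset(rng, 50, method="x")
        b = random_interval_callset(rng, 50, method="y")
        b.records = list(a.records)
        table = match_callsets(a, b)
        for svtype in INTERVAL_TYPES:
            assert table[svtype]["a_only"] == 0
            assert table[svtype]["shared"] == table[svtype]["n_a"]

    def test_type_stratification(self):
        a = SVCallset("S01", "x", records=[make_record(svtype="DEL", start=0, end=100)])
        b = SVCallset("S01", "y", records=[make_record(svtype="DUP", start=0, end=100)])
        table = match_callsets(a, b)
        assert table["DEL"]["shared"] == 0
        assert table["DEL"]["a_only"] == 1
        assert table["DUP"]["b_only"] == 1

    def test_sample_mismatch_raises_unless_overridden(self):
        a = SVCallset("S01", "x", records=[make_record()])
        b = SVCallset("S02", "y", records=[make_record(sample="S02")])
        with pytest.raises(ValueError, match="different samples"):
            match_callsets(a, b)
        match_callsets(a, b, allow_sample_mismatch=True)  # no raise

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("fraction", [0.5, 0.7, 0.9])
    def test_matches_brute_force_oracle(self, seed, fraction):
        rng = np.random.default_rng(seed)
        a = random_interval_callset(rng, 120, method="x")
        b = random_interval_callset(rng, 120, method="y")
        cfg = MatchConfig(fraction=fraction)
        table = match_callsets(a, b, cfg)
        expected = brute_force_table(a, b, cfg)
        for svtype in INTERVAL_TYPES:
            assert table[svtype] == expected[svtype], svtype

    def test_one_sided_mode_matches_brute_force(self):
        rng = np.random.default_rng(11)
        a = random_interval_callset(rng, 80, method="x")
        b = random_interval_callset(rng, 80, method="y")
        cfg = MatchConfig(fraction=0.7, reciprocal=False)
        table = match_callsets(a, b, cfg)
        expected = brute_force_table(a, b, cfg)
        for svtype in INTERVAL_TYPES:
            assert table[svtype] == expected[svtype], svtype

    def test_shared_count_non_increasing_in_fraction(self):
        rng = np.random.default_rng(4)
        a = random_interval_callset(rng, 150, method="x")
        b = random_interval_callset(rng, 150, method="y")
        previous = None
        for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            total_shared = sum(
                match_callsets(a, b, MatchConfig(fraction=f))[t]["shared"]
                for t in INTERVAL_TYPES
            )
            if previous is not None:
                assert total_shared <= previous
            previous = total_shared


class TestMatchTranslocations:
    def test_identical_events_match_at_any_window(self):
        ev = make_event()
        assert translocation_match(ev, ev, window=0)

    def test_different_chrom_pairs_never_match(self):
        a = make_event(chrom_a="14", chrom_b="4")
        b = make_event(chrom_a="14", chrom_b="11")
        assert not translocation_match(a, b, window=10**9)

    def test_window_boundary_is_inclusive(self):
        w = 10_000
        a = make_event(pos_a=1_000_000, pos_b=2_000_000)
        at_w = make_event(pos_a=1_000_000 + w, pos_b=2_000_000)
        beyond = make_event(pos_a=1_000_000 + w + 1, pos_b=2_000_000)
        assert translocation_match(a, at_w, window=w)
        assert not translocation_match(a, beyond, window=w)

    def test_breakend_correspondence_minimizes_max_displacement(self):
        # same-chromosome pair: the favorable pairing must be chosen
        a = make_event(chrom_a="1", pos_a=100, chrom_b="1", pos_b=5000)
        b = make_event(chrom_a="1", pos_a=5001, chrom_b="1", pos_b=101)
        assert translocation_match(a, b, window=10)

    def test_counts_directional(self):
        a = SVCallset("S01", "x", translocations=[
            make_event(pos_a=100, pos_b=200),
            make_event(chrom_a="6", pos_a=999_999, pos_b=5),
        ])
        b = SVCallset("S01", "y", translocations=[
            make_event(pos_a=150, pos_b=260),
        ])
        out = match_translocations(a, b, MatchConfig(translocation_window=1000))
        assert out == {"n_a": 2, "n_b": 1, "shared": 1, "a_only": 1, "b_only": 0}


class TestTypeComposition:
    def test_single_type(self):
        cs = SVCallset("S01", "x", records=[make_record(svtype="DEL")])
        assert type_composition(cs)["DEL"] == 1.0

    def test_known_count_vector(self):
        records = []
        for svtype, n in (("DEL", 56), ("INS", 33), ("DUP", 3), ("INV", 1)):
            for i in range(n):
                records.append(make_record(record_id=f"{svtype}{i}", svtype=svtype,
                                           start=i * 10, end=i * 10 + 5))
        cs = SVCallset("S01", "x", records=records,
                       translocations=[make_event(ids=(f"t{i}", f"t{i}'"))
                                       for i in range(7)])
        comp = type_composition(cs)
        assert comp == pytest.approx(
            {"DEL": 0.56, "INS": 0.33, "BND": 0.07, "DUP": 0.03, "INV": 0.01}
        )
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_callset_is_an_error(self):
        with pytest.raises(ValueError, match="no calls"):
            type_composition(SVCallset("S01", "x"))
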