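"""Somatic filter cascade, overlap keying, and the driver-gene matrix."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svconcord.short_variants import (
    DEFAULT_DRIVER_GENES,
    FilterConfig,
    RULE_NAMES,
    ShortVariant,
    apply_filter_cascade,
    driver_gene_matrix,
    left_normalize,
    read_variant_table,
    three_way_overlap,
)
from svconcord.synthetic import generate_short_variants, write_variant_table


def variant(**kwargs):
    base = dict(chrom="1", pos=1000, ref="A", alt="T", qual=60.0, depth=50,
                vaf=0.15, sor=1.0)
    base.update(kwargs)
    return ShortVariant(**base)


#: one engineered failure per cascade rule, in cascade order
RULE_BREAKER_VARIANTS = {
    "caller_filters": variant(filters=frozenset({"t_lod_fstar"})),
    "region": variant(region_class="intronic"),
    "function": variant(exonic_function="synonymous"),
    "pop_af": variant(pop_af=(0.05, None, 0.0)),
    "qual": variant(qual=39.9),
    "depth": variant(depth=9),
    "vaf": variant(vaf=0.01),
    "sor": variant(sor=3.5),
}


class TestFilterCascade:
    def test_low_vaf_removed_by_vaf_rule(self):
        kept, trace = apply_filter_cascade([variant(vaf=0.01)])
        assert kept == []
        assert trace.removed_by_rule["vaf"] == 1

    def test_high_vaf_also_removed(self):
        kept, _ = apply_filter_cascade([variant(vaf=0.31)])
        assert kept == []
        kept, _ = apply_filter_cascade([variant(vaf=0.30)])
        assert len(kept) == 1

    def test_sor_bound_differs_for_snv_and_indel(self):
        snv = variant(sor=3.5)
        deletion = variant(ref="ATT", alt="A", sor=3.5)
        kept, trace = apply_filter_cascade([snv, deletion])
        assert [v.variant_class for v in kept] == ["deletion"]
        assert trace.removed_by_rule["sor"] == 1
        kept, _ = apply_filter_cascade([variant(ref="ATT", alt="A", sor=11.5)])
        assert kept == []

    def test_one_fail_per_rule_fixture(self):
        variants = [RULE_BREAKER_VARIANTS[name] for name in RULE_NAMES]
        kept, trace = apply_filter_cascade(variants)
        assert kept == []
        assert trace.kept == 0
        assert trace.n_input == 8
        assert all(trace.removed_by_rule[name] == 1 for name in RULE_NAMES)

    def test_absent_population_af_is_kept(self):
        kept, _ = apply_filter_cascade([variant(pop_af=(None, None, None))])
        assert len(kept) == 1

    def test_kept_set_invariant_under_rule_reordering(self):
        variants = list(RULE_BREAKER_VARIANTS.values()) + [variant(), variant(pos=2)]
        baseline, _ = apply_filter_cascade(variants)
        for order in itertools.islice(itertools.permutations(RULE_NAMES), 0, 40, 7):
            kept, trace = apply_filter_cascade(variants, rule_order=list(order))
            assert kept == baseline
            assert trace.check_conservation()

    def test_tightening_a_threshold_never_keeps_more(self):
        variants = generate_short_variants(
            300, {"qual": 0.2, "vaf": 0.2, "sor": 0.1}, seed=5
        )
        loose, _ = apply_filter_cascade(variants, FilterConfig())
        for tighter in (
            FilterConfig(min_qual=60),
            FilterConfig(min_depth=50),
            FilterConfig(vaf_window=(0.05, 0.20)),
            FilterConfig(max_sor_snv=1.0),
            FilterConfig(max_pop_af=0.0001),
        ):
            kept, _ = apply_filter_cascade(variants, tighter)
            assert len(kept) <= len(loose)
            assert set(id(v) for v in kept) <= set(id(v) for v in loose)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.builds(
                variant,
                qual=st.floats(0, 100, allow_nan=False),
                depth=st.integers(0, 200),
                vaf=st.floats(0, 1, allow_nan=False),
                sor=st.floats(0, 20, allow_nan=False),
                region_class=st.sampled_from(["exonic", "intronic", "intergenic"]),
                exonic_function=st.sampled_from(
                    ["nonsynonymous", "synonymous", "frameshift", "nonframeshift"]
                ),
            ),
            max_size=40,
        )
    )
    def test_conservation_on_arbitrary_inputs(self, variants):
        kept, trace = apply_filter_cascade(variants)
        assert trace.check_conservation()
        assert trace.kept == len(kept)

    def test_malformed_row_reports_index(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tregion_class\texonic_function\taf1\taf2\taf3"
            "\tqual\tdepth\tvaf\tsor\tgene\tfilters\n"
            "1\t100\tA\tT\texonic\tnonsynonymous\t0\t0\t0\t60\t50\t0.15\t1\tKRAS\tPASS\n"
            "1\tnotanumber\tA\tT\texonic\tnonsynonymous\t0\t0\t0\t60\t50\t0.15\t1\t\tPASS\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_variant_table(path)


class TestLeftNormalize:
    @pytest.mark.parametrize("pos, ref, alt, expected", [
        (100, "A", "T", (100, "A", "T")),
        (100, "CTT", "CT", (100, "CT", "C")),     # suffix trim
        (100, "ACG", "AG", (100, "AC", "A")),
        (100, "TA", "TAA", (100, "T", "TA")),
        (100, "GCC", "GC", (100, "GC", "G")),
    ])
    def test_minimal_representation(self, pos, ref, alt, expected):
        assert left_normalize(pos, ref, alt) == expected

    def test_equivalent_representations_share_a_key(self):
        a = variant(pos=100, ref="CTT", alt="CT")
        b = variant(pos=100, ref="CT", alt="C")
        assert a.normalized_key() == b.normalized_key()


class TestThreeWayOverlap:
    def test_identical_sets_all_triple(self):
        vs = [variant(pos=p) for p in (1, 2, 3)]
        out = three_way_overlap(vs, list(vs), list(vs))
        assert out["abc"] == 3
        assert sum(out.values()) == 3

    def test_pairwise_disjoint_sets(self):
        a = [variant(pos=1)]
        b = [variant(pos=2)]
        c = [variant(pos=3), variant(pos=4)]
        out = three_way_overlap(a, b, c)
        assert out == {"a_only": 1, "b_only": 1, "c_only": 2,
                       "ab": 0, "ac": 0, "bc": 0, "abc": 0}

    def test_random_sets_match_set_algebra_and_partition_the_union(self):
        import random

        rng = random.Random(17)
        pool = [variant(pos=p) for p in range(40)]
        a = rng.sample(pool, 20)
        b = rng.sample(pool, 25)
        c = rng.sample(pool, 10)
        out = three_way_overlap(a, b, c)
        ka, kb, kc = ({v.normalized_key() for v in s} for s in (a, b, c))
        assert out["abc"] == len(ka & kb & kc)
        assert out["ab"] == len((ka & kb) - kc)
        assert out["a_only"] == len(ka - kb - kc)
        assert sum(out.values()) == len(ka | kb | kc)


class TestDriverGeneMatrix:
    def test_default_panel_columns(self):
        matrix = driver_gene_matrix({("S01", "WES"): []})
        assert list(matrix.columns) == list(DEFAULT_DRIVER_GENES)
        assert matrix.values.sum() == 0

    def test_single_hit_sets_exactly_one_cell(self):
        groups = {
            ("S01", "WES"): [variant(gene="NRAS")],
            ("S01", "linked-read"): [],
        }
        matrix = driver_gene_matrix(groups)
        assert matrix.values.sum() == 1
        assert matrix.loc[("S01", "WES"), "NRAS"] == 1

    def test_unknown_dataset_label_is_an_error(self):
        with pytest.raises(ValueError, match="dataset"):
            driver_gene_matrix({("S01", "wgs"): []})

    def test_off_panel_genes_are_ignored(self):
        matrix = driver_gene_matrix({("S01", "WES"): [variant(gene="TTN")]})
        assert matrix.values.sum() == 0


class TestVariantTableRoundTrip:
    def test_written_table_reads_back_identically(self, tmp_path):
        variants = generate_short_variants(50, {"vaf": 0.2, "sor": 0.1}, seed=9)
        path = tmp_path / "v.tsv"
        write_variant_table(variants, path)
        back = read_variant_table(path)
        assert len(back) == 50
        for orig, rt in zip(variants, back):
            assert (orig.chrom, orig.pos, orig.ref, orig.alt) == (
                rt.chrom, rt.pos, rt.ref, rt.alt
            )
            assert rt.pop_af == orig.pop_af
            assert rt.vaf == pytest.approx(orig.vaf)
            assert rt.filters == orig.filters
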