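"""Clinical panel construction and per-sample event scoring."""

import numpy as np
import pytest

from svconcord.cytogenetics import (
    CytoEventSpec,
    build_event_panel,
    build_prediction_matrix,
    detect_events,
)
from svconcord.io import ArmDefinition, GenomicInterval, SVCallset

from conftest import make_bnd_pair, make_event, make_record, random_interval_callset
from svconcord.io import pair_breakends


class TestBuildEventPanel:
    def test_ten_events_with_expected_kinds(self, panel):
        assert len(panel) == 10
        kinds = [spec.kind for spec in panel]
        assert kinds.count("arm_loss") == 4
        assert kinds.count("arm_gain") == 1
        assert kinds.count("translocation") == 5

    def test_event_ids_are_unique_and_clinical(self, panel):
        ids = [spec.event_id for spec in panel]
        assert len(set(ids)) == 10
        assert set(ids) == {
            "del(1p)", "gain(1q)", "del(13q)", "del(14q)", "del(17p)",
            "t(4;14)", "t(6;14)", "t(11;14)", "t(14;16)", "t(14;20)",
        }

    def test_del17p_region_equals_the_17p_arm(self, panel, arms):
        spec = next(s for s in panel if s.event_id == "del(17p)")
        assert spec.region == arms.get("17", "p")

    def test_igh_translocations_pair_chromosome_14(self, panel):
        for spec in panel:
            if spec.kind == "translocation":
                assert "14" in spec.chrom_pair

    def test_missing_chromosome_is_an_error(self):
        arms = ArmDefinition({("1", "p"): GenomicInterval("1", 0, 100),
                              ("1", "q"): GenomicInterval("1", 100, 200)})
        with pytest.raises(ValueError, match="13"):
            build_event_panel(arms)


class TestDetectEvents:
    def test_single_del_spanning_13q_scores_only_del13q(self, panel, arms):
        q13 = arms.get("13", "q")
        rec = make_record(svtype="DEL", chrom="13", start=q13.start + 1000,
                          end=q13.start + 200_000)
        row = detect_events(SVCallset("S01", "wes", records=[rec]), panel)
        assert row["del(13q)"] == 1
        assert sum(row.values()) == 1

    def test_empty_callset_scores_all_zero(self, panel):
        row = detect_events(SVCallset("S01", "wes"), panel)
        assert set(row) == {s.event_id for s in panel}
        assert all(v == 0 for v in row.values())

    def test_paired_bnd_joining_14_and_4_scores_t4_14(self, panel):
        rec_a, rec_b = make_bnd_pair(chrom_a="14", chrom_b="4")
        cs = pair_breakends(
            SVCallset("S01", "wes", records=[rec_a, rec_b],
                      unpaired_bnds=[rec_a, rec_b])
        )
        row = detect_events(cs, panel)
        assert row["t(4;14)"] == 1
        assert sum(row.values()) == 1

    def test_unpaired_bnds_never_support_translocation_events(self, panel):
        rec_a, _ = make_bnd_pair(chrom_a="14", chrom_b="4", mutual=False)
        cs = SVCallset("S01", "wes", records=[rec_a], unpaired_bnds=[rec_a])
        row = detect_events(cs, panel)
        assert row["t(4;14)"] == 0

    def test_foreign_chromosomes_warn_and_score_zero(self, panel):
        rec = make_record(chrom="Z", start=0, end=1000)
        with pytest.warns(UserWarning, match="no chromosomes"):
            row = detect_events(SVCallset("S01", "wes", records=[rec]), panel)
        assert all(v == 0 for v in row.values())

    def test_non_pass_records_are_excluded_by_default(self, panel, arms):
        q13 = arms.get("13", "q")
        rec = make_record(svtype="DEL", chrom="13", start=q13.start,
                          end=q13.start + 1000, filters=("MinQual",))
        cs = SVCallset("S01", "wes", records=[rec])
        assert detect_events(cs, panel)["del(13q)"] == 0
        assert detect_events(cs, panel, pass_only=False)["del(13q)"] == 1

    def test_min_sv_size_threshold_applies(self, arms):
        q13 = arms.get("13", "q")
        spec = CytoEventSpec(event_id="del(13q)", kind="arm_loss", region=q13,
                             min_sv_size=1000)
        small = make_record(svtype="DEL", chrom="13", start=q13.start,
                            end=q13.start + 100)
        large = make_record(record_id="r2", svtype="DEL", chrom="13",
                            start=q13.start, end=q13.start + 5000)
        row = detect_events(SVCallset("S01", "wes", records=[small, large]), [spec])
        assert row["del(13q)"] == 1

    def test_score_monotone_under_added_records(self, panel, arms):
        rng = np.random.default_rng(8)
        chroms = [c for c, _ in arms.arms.keys()]
        cs = random_interval_callset(rng, 0, chroms=chroms)
        prev = detect_events(cs, panel)
        for i in range(30):
            extra = random_interval_callset(rng, 1, chroms=sorted(set(chroms)),
                                            span=50_000_000).records
            cs.records.extend(extra)
            row = detect_events(cs, panel)
            assert all(row[e] >= prev[e] for e in row)
            prev = row

    def test_matches_brute_force_per_record_loop(self, panel, arms):
        rng = np.random.default_rng(21)
        chroms = sorted({c for c, _ in arms.arms.keys()})
        cs = random_interval_callset(rng, 200, chroms=chroms, span=100_000_000,
                                    max_len=2_000_000)
        cs.translocations = [
            make_event(chrom_a=chroms[rng.integers(len(chroms))],
                       chrom_b=chroms[rng.integers(len(chroms))],
                       pos_a=int(rng.integers(10**6)), pos_b=int(rng.integers(10**6)),
                       ids=(f"e{i}:0", f"e{i}:1"))
            for i in range(40)
        ]
        row = detect_events(cs, panel)
        for spec in panel:
            if spec.kind == "translocation":
                expected = sum(
                    1 for ev in cs.translocations
                    if ev.breakend_a.chrom != ev.breakend_b.chrom
                    and tuple(sorted((ev.breakend_a.chrom, ev.breakend_b.chrom)))
                    == spec.chrom_pair
                )
            else:
                svtype = "DEL" if spec.kind == "arm_loss" else "DUP"
                expected = sum(
                    1 for rec in cs.records
                    if rec.svtype == svtype
                    and rec.interval.chrom == spec.region.chrom
                    and rec.interval.start < spec.region.end
                    and rec.interval.end > spec.region.start
                )
            assert row[spec.event_id] == expected, spec.event_id


class TestBuildPredictionMatrix:
    def test_full_grid_shape(self, panel, arms):
        callsets = [
            SVCallset(f"S{i:02d}", method, records=[])
            for i in range(8) for method in ("wes", "linked-read")
        ]
        matrices = build_prediction_matrix(callsets, panel)
        assert set(matrices) == {"wes", "linked-read"}
        for pm in matrices.values():
            assert pm.table.shape == (8, 10)
            assert pm.table.values.sum() == 0

    def test_duplicate_sample_method_is_an_error(self, panel):
        callsets = [SVCallset("S01", "wes"), SVCallset("S01", "wes")]
        with pytest.raises(ValueError, match="duplicate"):
            build_prediction_matrix(callsets, panel)

    def test_zero_callsets_is_an_error(self, panel):
        with pytest.raises(ValueError, match="no callsets"):
            build_prediction_matrix([], panel)

    def test_scores_invariant_to_record_order(self, panel, arms):
        rng = np.random.default_rng(5)
        chroms = sorted({c for c, _ in arms.arms.keys()})
        cs = random_interval_callset(rng, 100, chroms=chroms, span=80_000_000,
                                    max_len=1_000_000)
        row = detect_events(cs, panel)
        shuffled = SVCallset(cs.sample, cs.method, records=list(reversed(cs.records)))
        assert detect_events(shuffled, panel) == row
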