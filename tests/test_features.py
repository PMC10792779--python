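"""Breakpoint window statistics, repeat flags, support block, matrix assembly."""

import numpy as np
import pytest

import svjudge as sj
from svjudge.features import SCHEMA, schema_hash


def _read(pos, cigar, mapq=60, name=None, proper=True, mate=None, quals=None, chrom="chr1"):
    return sj.AlignedReadView(
        name=name or f"r{pos}", chrom=chrom, pos=pos, mapq=mapq, cigar=cigar,
        is_proper_pair=proper,
        mate_chrom=None if mate is None else mate[0],
        mate_pos=None if mate is None else mate[1],
        base_qualities=quals or [30] * sum(n for op, n in cigar if op in "MIS=X"),
    )


BP = sj.Breakpoint("chr1", 1000)
CFG = sj.FeatureConfig()


class TestWindowStats:
    def test_empty_window_imputes_and_flags(self):
        out = sj.window_stats([], BP, CFG)
        assert out["depth"] == 0 and out["clip_count"] == 0
        assert out["clip_len_mean"] == 0 and out["mapq_mean"] == 0
        assert out["no_reads"] == 1

    def test_clip_statistics_match_enumeration(self):
        # five reads in window, two soft-clipped with clip lengths 3 and 7
        reads = [
            _read(950, [("M", 100)]),
            _read(960, [("M", 100)]),
            _read(970, [("M", 100)]),
            _read(905, [("M", 97), ("S", 3)]),   # right clip boundary at 1002
            _read(1010, [("S", 7), ("M", 93)]),  # left clip boundary at 1010
        ]
        out = sj.window_stats(reads, BP, CFG)
        assert out["depth"] == 5
        assert out["clip_count"] == 2
        assert (out["clip_len_min"], out["clip_len_max"], out["clip_len_mean"]) == (3, 7, 5)

    def test_default_window_spans_plus_minus_20(self):
        inside = _read(999, [("M", 100)])       # overlaps [980, 1020)
        outside_left = _read(880, [("M", 100)])  # ends at 980, half-open miss
        outside_right = _read(1020, [("M", 100)])
        out = sj.window_stats([inside, outside_left, outside_right], BP, CFG)
        assert out["depth"] == 1

    def test_clip_outside_window_not_counted(self):
        r = _read(900, [("M", 50), ("S", 10)])  # boundary at 950, outside window
        out = sj.window_stats([r], sj.Breakpoint("chr1", 920), CFG)
        assert out["depth"] == 1 and out["clip_count"] == 0

    def test_discordant_requires_mate_near_partner(self):
        partner = sj.Breakpoint("chr5", 50_000)
        near = _read(990, [("M", 100)], proper=False, mate=("chr5", 50_400))
        far = _read(995, [("M", 100)], proper=False, mate=("chr5", 90_000))
        other_chrom = _read(996, [("M", 100)], proper=False, mate=("chr9", 50_000))
        out = sj.window_stats([near, far, other_chrom], BP, CFG, partner=partner)
        assert out["discordant_count"] == 1

    def test_mapq_and_basequal_summaries(self):
        reads = [
            _read(950, [("M", 100)], mapq=60, quals=[40] * 100),
            _read(990, [("M", 100)], mapq=20, quals=[20] * 100),
        ]
        out = sj.window_stats(reads, BP, CFG)
        assert (out["mapq_min"], out["mapq_max"], out["mapq_mean"]) == (20, 60, 40)
        assert out["basequal_mean"] == 30


class TestRepeatFlags:
    def test_empty_track_gives_zero_flags(self):
        rec = sj.SVRecord(id="a", svtype="DEL", bp1=sj.Breakpoint("chr1", 150),
                          bp2=sj.Breakpoint("chr1", 500))
        assert sj.repeat_flags(rec, sj.RepeatTrack()) == (0, 0)

    def test_flag_set_only_for_breakpoint_inside_interval(self):
        track = sj.RepeatTrack([sj.GenomicInterval("chr1", 100, 200)])
        rec = sj.SVRecord(id="a", svtype="DEL", bp1=sj.Breakpoint("chr1", 150),
                          bp2=sj.Breakpoint("chr1", 500))
        assert sj.repeat_flags(rec, track) == (1, 0)
        # half-open: end coordinate is outside
        rec2 = sj.SVRecord(id="b", svtype="DEL", bp1=sj.Breakpoint("chr1", 200),
                           bp2=sj.Breakpoint("chr1", 500))
        assert sj.repeat_flags(rec2, track) == (0, 0)


class TestSupportFeatures:
    def test_dv_rv_sum_and_ratio(self):
        rec = sj.SVRecord(id="a", svtype="DEL", bp1=sj.Breakpoint("chr1", 1),
                          bp2=sj.Breakpoint("chr1", 2),
                          support=sj.SupportCounts(DV=10, RV=5))
        out = sj.support_features(rec)
        assert out["dv_rv_sum"] == 15
        assert out["rv_fraction"] == pytest.approx(1 / 3)
        assert out["rv_fraction_imputed"] == 0 and out["support_missing"] == 0

    def test_zero_denominator_imputed_with_indicator(self):
        rec = sj.SVRecord(id="a", svtype="DEL", bp1=sj.Breakpoint("chr1", 1),
                          bp2=sj.Breakpoint("chr1", 2),
                          support=sj.SupportCounts(DV=0, RV=0))
        out = sj.support_features(rec)
        assert out["rv_fraction"] == 0 and out["rv_fraction_imputed"] == 1

    def test_missing_counts_marked_not_zeroed_silently(self):
        rec = sj.SVRecord(id="a", svtype="DEL", bp1=sj.Breakpoint("chr1", 1),
                          bp2=sj.Breakpoint("chr1", 2))
        out = sj.support_features(rec)
        assert out["support_missing"] == 1 and out["dv"] == 0


class TestBuildFeatureMatrix:
    def test_empty_record_list_keeps_full_schema(self):
        fm = sj.build_feature_matrix([], [], None, CFG)
        assert len(fm) == 0 and list(fm.data.columns) == SCHEMA

    def test_all_three_feature_families_in_schema(self):
        window = [c for c in SCHEMA if "clip" in c or "depth" in c or "mapq" in c]
        repeat = [c for c in SCHEMA if "repeat" in c]
        support = [c for c in SCHEMA if c in ("dv", "rv", "dv_rv_sum", "rv_fraction")]
        assert window and len(repeat) == 2 and len(support) == 4

    def test_permuting_records_permutes_rows(self, spiked_dataset):
        ds, sv = spiked_dataset
        other = sj.SVRecord(id="bg_only", svtype="INV",
                            bp1=sj.Breakpoint("chr2", 1000), bp2=sj.Breakpoint("chr2", 9000))
        idx = sj.AlignmentIndex(ds.alignments)
        a = sj.build_feature_matrix([sv, other], idx, None, CFG)
        b = sj.build_feature_matrix([other, sv], idx, None, CFG)
        assert a.data.loc[sv.id].equals(b.data.loc[sv.id])
        assert a.data.loc["bg_only"].equals(b.data.loc["bg_only"])

    def test_deterministic_and_finite(self, spiked_dataset):
        ds, sv = spiked_dataset
        a = sj.build_feature_matrix([sv], ds.alignments, None, CFG)
        b = sj.build_feature_matrix([sv], ds.alignments, None, CFG)
        assert a.data.equals(b.data)
        assert np.isfinite(a.values()).all()
        assert a.schema_hash == schema_hash()

    def test_locality_far_reads_do_not_change_features(self, spiked_dataset):
        ds, sv = spiked_dataset
        far = [r for r in ds.alignments if
               min(abs(r.pos - sv.bp1.pos), abs(r.pos - sv.bp2.pos)) > 200
               and min(abs(r.reference_end - sv.bp1.pos), abs(r.reference_end - sv.bp2.pos)) > 200]
        a = sj.build_feature_matrix([sv], ds.alignments, None, CFG)
        b = sj.build_feature_matrix([sv], [r for r in ds.alignments if r not in far[:50]], None, CFG)
        assert a.data.equals(b.data)

    def test_breakpoint_outside_territory_warns_with_empty_window(self, spiked_dataset):
        ds, _ = spiked_dataset
        rec = sj.SVRecord(id="offmap", svtype="BND",
                          bp1=sj.Breakpoint("chr2", 5000), bp2=sj.Breakpoint("chr17", 100))
        with pytest.warns(UserWarning, match="outside alignment territory"):
            fm = sj.build_feature_matrix([rec], ds.alignments, None, CFG)
        assert fm.data.loc["offmap", "bp2_depth"] == 0
        assert fm.data.loc["offmap", "bp2_no_reads"] == 1

    def test_spiked_sv_shows_clip_and_discordant_signal(self, spiked_dataset):
        ds, sv = spiked_dataset
        quiet = sj.SVRecord(id="quiet", svtype="DEL",
                            bp1=sj.Breakpoint("chr2", 1000), bp2=sj.Breakpoint("chr2", 9000))
        fm = sj.build_feature_matrix([sv, quiet], ds.alignments, None, CFG)
        assert fm.data.loc[sv.id, "bp1_clip_count"] > 5 * max(1.0, fm.data.loc["quiet", "bp1_clip_count"])
        assert fm.data.loc[sv.id, "bp1_discordant_count"] > 0

    def test_duplicate_ids_rejected(self):
        rec = sj.SVRecord(id="dup", svtype="DEL", bp1=sj.Breakpoint("chr1", 1),
                          bp2=sj.Breakpoint("chr1", 2))
        with pytest.raises(ValueError, match="unique"):
            sj.build_feature_matrix([rec, rec], [], None, CFG)
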