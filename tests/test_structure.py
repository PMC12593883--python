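"""Structural annotation: subfamily calls, segmentation, hotspots, mining."""

import pytest
from hypothesis import given, strategies as st

from svatrx.repeats import decompose_tandem, minimal_period
from svatrx.structure import (
    AMBIGUOUS,
    UNCLASSIFIABLE,
    StructureAnnotation,
    mine_hexamer_patterns,
    summarize_regions,
)
from dp_oracle import brute_force_periods


def _truth_ok(call: str, row) -> bool:
    if call == row.subfamily:
        return True
    # abstention is the correct answer when no F/F1 evidence survives
    return call == AMBIGUOUS and row.subfamily in ("F", "F1") and not row.f_f1_informative


class TestSubfamily:
    def test_unmutated_accuracy_is_total(self, pipeline200):
        truth = pipeline200.truth
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role == "orphan":
                assert s.subfamily == UNCLASSIFIABLE
                continue
            assert _truth_ok(s.subfamily, row), (s.insertion_id, row.subfamily, s.subfamily)

    def test_mutated_accuracy_and_no_bin_confusion(self, pipeline_mutated):
        """>= 95% accuracy at the default mutation rate; F/F1 never confused
        with D or E."""
        truth = pipeline_mutated.truth
        n = ok = 0
        for s in pipeline_mutated.structures:
            row = truth.loc[s.insertion_id]
            if row.role == "orphan":
                continue
            n += 1
            correct = s.subfamily == row.subfamily or (
                s.subfamily == AMBIGUOUS and row.subfamily in ("F", "F1")
            )
            ok += correct
            if row.subfamily in ("F", "F1"):
                assert s.subfamily not in ("D", "E"), s.insertion_id
            if row.subfamily in ("D", "E"):
                assert s.subfamily in ("D", "E"), s.insertion_id
        assert ok / n >= 0.95

    def test_full_length_f1_has_large_mast2_block(self, pipeline200):
        truth = pipeline200.truth
        seen = 0
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.subfamily == "F1" and row.truncation == "none":
                assert s.subfamily == "F1"
                assert s.mast2_bp > 320
                seen += 1
        assert seen >= 5

    def test_uninformative_truncation_is_ambiguous(self, pipeline200):
        truth = pipeline200.truth
        cases = truth[(~truth.f_f1_informative) & (truth.role == "sva")]
        for rec_id in cases.index:
            s = pipeline200.structures_by_id[rec_id]
            assert s.subfamily == AMBIGUOUS


class TestSegmentation:
    def test_full_length_regions_exact(self, pipeline200):
        """Recovered region boundaries equal the truth for unmutated
        full-length elements."""
        truth = pipeline200.truth
        checked = 0
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role != "sva" or row.truncation != "none":
                continue
            expected = pipeline200.details[s.insertion_id]["regions"]
            for name, iv in expected.items():
                assert s.regions.get(name) == tuple(iv), (s.insertion_id, name)
            checked += 1
        assert checked >= 80

    def test_truncated_in_vntr_flags_vntr(self, pipeline200):
        truth = pipeline200.truth
        seen = 0
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role == "sva" and row.truncation == "5p" and row.vntr_len != row.vntr_len:
                # NaN vntr_len marks truncation within (or upstream of) the VNTR
                assert s.vntr_length is None
                assert "hexamer" not in s.regions and "alu_like" not in s.regions or (
                    s.hexamer_length == 0
                )
                seen += 1
        assert seen >= 5

    def test_hexamer_and_polya_metrics_exact(self, pipeline200):
        truth = pipeline200.truth
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role != "sva":
                continue
            assert s.hexamer_length == row.hexamer_len, s.insertion_id
            assert s.polya_length == row.polya_len
            assert s.mast2_bp == row.mast2_bp

    def test_vntr_length_exact_when_defined(self, pipeline200):
        truth = pipeline200.truth
        n = 0
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role != "sva":
                continue
            if s.vntr_length is not None:
                assert s.vntr_length == row.vntr_len, s.insertion_id
                n += 1
        assert n >= 80

    def test_region_tiling_within_insertion(self, pipeline200):
        """Regions are ordered, non-overlapping and inside the insertion."""
        by_id = {r.id: r for r in pipeline200.passing}
        for s in pipeline200.structures:
            seq_len = len(by_id[s.insertion_id].sequence)
            last = 0
            for name, (a, b) in s.regions.items():
                assert 0 <= a <= b <= seq_len
                assert a >= last, (s.insertion_id, name)
                last = b


class TestTruncation:
    def test_classes_recovered(self, pipeline200):
        truth = pipeline200.truth
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role != "sva":
                continue
            assert s.truncation == row.truncation, s.insertion_id
            assert s.full_length == (row.truncation == "none")

    def test_offsets_exact(self, pipeline200):
        truth = pipeline200.truth
        n = 0
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role == "sva" and row.truncation in ("3p", "both"):
                assert s.truncation_offset_3prime == row.trunc3_offset, s.insertion_id
                n += 1
        assert n >= 3

    def test_hotspots_and_cryptic_signals(self, pipeline200):
        truth = pipeline200.truth
        for s in pipeline200.structures:
            row = truth.loc[s.insertion_id]
            if row.role != "sva":
                continue
            expected = row.hotspot if row.hotspot in ("H233", "H323") else "none"
            assert s.hotspot == expected, s.insertion_id
            if row.hotspot in ("H233", "H323"):
                assert s.cryptic_signal_found
                expected = "(G->A)TTAAA" if row.hotspot == "H233" else "AAGAAA"
                assert s.cryptic_signal == expected

    def test_marker_substitution_without_truncation_reported(self, pipeline200):
        truth = pipeline200.truth
        markers = truth[(truth.hotspot_marker) & (truth.role == "sva")]
        if len(markers) == 0:
            pytest.skip("no marker carriers drawn in this cohort")
        for rec_id in markers.index:
            assert pipeline200.structures_by_id[rec_id].cryptic_marker


class TestHexamerMining:
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=60).filter(lambda s: len(set(s)) > 1)
    )
    def test_minimal_period_matches_brute_force(self, s):
        assert minimal_period(s) == brute_force_periods(s)

    @pytest.mark.parametrize(
        "region,unit,copies",
        [
            ("CCCTCT" * 6, "CCCTCT", 6),
            ("CCGTCT" * 4, "CCGTCT", 4),
        ],
    )
    def test_unit_decomposition(self, region, unit, copies):
        got_unit, got_copies, rem = decompose_tandem(region)
        assert (got_unit, got_copies, rem) == (unit, copies, 0)

    def test_composite_pattern_reported_with_count(self):
        """A 16-mer unit planted in 7 elements surfaces at min_share 5."""
        unit16 = "CCCTCTCCGTCTGCTT"
        anns = []
        for i in range(7):
            anns.append(
                StructureAnnotation(
                    insertion_id=f"a{i}", subfamily="E",
                    regions={"hexamer": (0, 16 * 3)},
                    hexamer_unit=unit16, hexamer_length=16 * 3,
                )
            )
        for i in range(3):  # below min_share
            anns.append(
                StructureAnnotation(
                    insertion_id=f"b{i}", subfamily="E",
                    regions={"hexamer": (0, 12)},
                    hexamer_unit="CCGTCT", hexamer_length=12,
                )
            )
        table = mine_hexamer_patterns(anns, min_share=5)
        assert list(table.pattern) == [unit16]
        assert int(table.n_elements.iloc[0]) == 7

    def test_cohort_patterns_recover_planted_units(self, pipeline200):
        cfg = pipeline200.sim.config
        table = mine_hexamer_patterns(pipeline200.structures, min_share=5)
        planted = {u for u, _ in cfg.hexamer_patterns}
        assert planted <= set(table.pattern)


class TestSummaries:
    def test_vntr_ordering_recovers_planted_means(self, pipeline200):
        """Younger subfamilies were planted with longer VNTRs: F1 > F >= E > D."""
        df = summarize_regions(pipeline200.structures).set_index("subfamily")
        means = df.vntr_mean
        assert means["F1"] > means["F"] >= means["E"] > means["D"]

    def test_single_element_stats_degenerate(self):
        ann = StructureAnnotation(
            insertion_id="x", subfamily="E",
            regions={"hexamer": (0, 12)},
            hexamer_unit="CCCTCT", hexamer_length=12,
            vntr_length=500, polya_length=30, full_length=True,
        )
        df = summarize_regions([ann]).set_index("subfamily")
        assert df.loc["E", "vntr_mean"] == df.loc["E", "vntr_median"] == 500

    def test_vntr_stats_exclude_truncated(self, pipeline200):
        truth = pipeline200.truth
        df = summarize_regions(pipeline200.structures).set_index("subfamily")
        # every VNTR value entering the stats came from an untruncated VNTR
        complete = truth[(truth.role == "sva") & truth.vntr_len.notna()]
        for sub in ("D", "E", "F", "F1"):
            vals = complete[complete.subfamily == sub].vntr_len
            if sub in df.index and len(vals):
                assert df.loc[sub, "vntr_max"] <= vals.max()
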