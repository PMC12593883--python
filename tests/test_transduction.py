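"""Transduction extraction, origin tracing, grouping and summaries."""

import collections

import numpy as np
import pytest

from svatrx.transduction import (
    TransductionCall,
    TransductionParams,
    group_tds,
    summarize_tds,
    trace_origin,
)


def _calls_by_id(pipeline):
    out = collections.defaultdict(list)
    for c in pipeline.calls:
        out[c.insertion_id].append(c)
    return out


class TestExtraction:
    def test_cargo_intervals_match_truth(self, pipeline200):
        """Extracted cargo intervals equal the planted ones exactly."""
        calls_by = _calls_by_id(pipeline200)
        checked = 0
        for rec_id, detail in pipeline200.details.items():
            segs = detail["td_segments"]
            if not segs or rec_id not in pipeline200.structures_by_id:
                continue
            for side in {s["side"] for s in segs}:
                side_segs = [s for s in segs if s["side"] == side]
                call = next(c for c in calls_by[rec_id] if c.side == side)
                lo = min(s["cargo_start"] for s in side_segs)
                hi = max(s["cargo_end"] for s in side_segs)
                assert call.cargo_interval == (lo, hi), rec_id
                checked += 1
        assert checked >= 50

    def test_no_cargo_no_candidates(self, pipeline200):
        calls_by = _calls_by_id(pipeline200)
        truth = pipeline200.truth
        for rec_id, row in truth.iterrows():
            if row.role == "sva" and not row.td5 and not row.td3:
                assert rec_id not in calls_by

    def test_orphan_candidate_emitted(self, pipeline200):
        truth = pipeline200.truth
        orphan_ids = set(truth[truth.role == "orphan"].index)
        flagged = {c.insertion_id for c in pipeline200.calls if c.orphan}
        assert orphan_ids == flagged

    def test_mast2_never_extracted_as_cargo(self, pipeline200):
        """The MAST2 block is F1 structure, not a 5' transduction."""
        truth = pipeline200.truth
        calls_by = _calls_by_id(pipeline200)
        f1_no_td = truth[
            (truth.subfamily == "F1") & (truth.role == "sva") & (~truth.td5)
        ]
        assert len(f1_no_td) >= 10
        for rec_id in f1_no_td.index:
            assert all(c.side != "5p" for c in calls_by.get(rec_id, []))

    def test_minimum_cargo_respected(self, pipeline200):
        for c in pipeline200.calls:
            assert len(c.cargo) >= 9


class TestTracing:
    def test_origins_exact_for_long_cargo(self, pipeline200):
        """Precision and recall 100% for cargo >= 20 bp on unmutated data."""
        calls_by = _calls_by_id(pipeline200)
        n = 0
        for rec_id, detail in pipeline200.details.items():
            if rec_id not in pipeline200.structures_by_id:
                continue
            for side in {s["side"] for s in detail["td_segments"]}:
                side_segs = [s for s in detail["td_segments"] if s["side"] == side]
                call = next(c for c in calls_by[rec_id] if c.side == side)
                if len(call.cargo) < 20:
                    continue
                assert not call.untraced, rec_id
                assert len(call.origins) == len(side_segs), rec_id
                for origin, seg in zip(call.origins, side_segs):
                    assert origin.chrom == seg["chrom"]
                    assert abs(origin.start - seg["start"]) <= 3
                    assert abs(origin.end - seg["end"]) <= 3
                n += 1
        assert n >= 50

    def test_short_cargo_recall_and_precision(self, pipeline200):
        """9-19 bp cargo: recall >= 90% and every accepted origin correct."""
        calls_by = _calls_by_id(pipeline200)
        total = traced = 0
        for rec_id, detail in pipeline200.details.items():
            if rec_id not in pipeline200.structures_by_id:
                continue
            for side in {s["side"] for s in detail["td_segments"]}:
                side_segs = [s for s in detail["td_segments"] if s["side"] == side]
                call = next(c for c in calls_by[rec_id] if c.side == side)
                if len(call.cargo) >= 20:
                    continue
                total += 1
                if call.untraced:
                    continue
                traced += 1
                seg = side_segs[0]
                assert call.origins[0].chrom == seg["chrom"]
                assert abs(call.origins[0].start - seg["start"]) <= 3
        if total:
            assert traced / total >= 0.9

    def test_concatenated_cargo_yields_ordered_segments(self, pipeline200):
        truth = pipeline200.truth
        conc = truth[truth.concatenated & (truth.role == "sva")]
        assert len(conc) >= 1
        calls_by = _calls_by_id(pipeline200)
        for rec_id in conc.index:
            call = next(c for c in calls_by[rec_id] if c.side == "3p")
            assert call.concatenated
            starts = [o.cargo_start for o in call.origins]
            assert starts == sorted(starts)

    def test_ultra_short_flagged_at_source_flank(self, pipeline200):
        truth = pipeline200.truth
        ultra = truth[truth.ultra_short]
        assert len(ultra) == pipeline200.sim.config.ultra_short_count
        calls_by = _calls_by_id(pipeline200)
        for rec_id in ultra.index:
            call = next(c for c in calls_by[rec_id] if c.side == "3p")
            assert call.ultra_short_source_tsd
            assert not call.untraced

    def test_origin_with_polya_downstream_rejected(self):
        """A locus followed by a genomic poly-A is an offspring copy, not the
        origin."""
        rng = np.random.default_rng(3)
        cargo = "".join(rng.choice(list("ACGT"), 60))
        bg = "".join(rng.choice(list("ACGT"), 400))
        true_origin = bg[:100] + cargo + bg[100:200]
        decoy = bg[200:300] + cargo + "A" * 40 + bg[300:]
        origins, untraced = trace_origin(cargo, {"chrA": true_origin, "chrB": decoy})
        assert not untraced
        assert [o.chrom for o in origins] == ["chrA"]
        assert origins[0].start == 100


class TestGrouping:
    def test_groups_partition_calls(self, pipeline200):
        groups = collections.defaultdict(list)
        for c in pipeline200.calls:
            if c.group is not None:
                groups[c.group].append(c)
        for gid, members in groups.items():
            assert len(members) >= 2
        # every traced call is in exactly one group or a singleton (group None)
        for c in pipeline200.calls:
            if c.origins:
                assert c.group is None or c.group in groups

    def test_shared_origin_offspring_share_group(self, pipeline200):
        """Offspring of one source fall into one TD group."""
        source_truth = pipeline200.sim.truth.sources
        calls_by = _calls_by_id(pipeline200)
        for row in source_truth.itertuples():
            if row.provenance == "lost" or row.n_offspring < 2:
                continue
            offspring = row.offspring.split(",")
            side_groups = collections.defaultdict(set)
            for rec_id in offspring:
                for c in calls_by.get(rec_id, []):
                    if c.origins and not c.untraced:
                        side_groups[c.side].add(c.group)
            for side, gids in side_groups.items():
                if len([r for r in offspring for c in calls_by.get(r, []) if c.side == side]) >= 2:
                    assert len(gids) == 1 and None not in gids, row.id

    def test_all_distinct_origins_all_singletons(self):
        calls = [
            TransductionCall(
                insertion_id=f"i{k}", side="3p", cargo="ACGT" * 10,
                cargo_interval=(0, 40),
            )
            for k in range(4)
        ]
        from svatrx.transduction import OriginLocus

        for k, c in enumerate(calls):
            c.origins = [OriginLocus("chr1", 10_000 * k, 10_000 * k + 40, 1.0)]
        groups = group_tds(calls)
        assert groups == {}
        assert all(c.group is None for c in calls)

    def test_concatenated_call_joins_group_via_any_segment(self):
        from svatrx.transduction import OriginLocus

        a = TransductionCall("a", "3p", "A" * 40, (0, 40))
        b = TransductionCall("b", "3p", "A" * 40, (0, 40))
        c = TransductionCall("c", "3p", "A" * 80, (0, 80))
        a.origins = [OriginLocus("chr1", 100, 140, 1.0)]
        b.origins = [OriginLocus("chr1", 105, 145, 1.0)]
        c.origins = [
            OriginLocus("chr2", 500, 540, 1.0),
            OriginLocus("chr1", 102, 142, 1.0, cargo_start=40, cargo_end=80),
        ]
        groups = group_tds([a, b, c])
        assert len(groups) == 1
        assert {x.insertion_id for x in next(iter(groups.values()))} == {"a", "b", "c"}


class TestSummaries:
    def test_counts_partition_cohort(self, pipeline200):
        s = summarize_tds(pipeline200.calls, len(pipeline200.passing))
        assert (
            s["n_5p_only"] + s["n_3p_only"] + s["n_both"] + s["n_none"]
            == len(pipeline200.passing)
        )

    def test_td_rate_within_binomial_ci_of_planted(self, pipeline200):
        cfg = pipeline200.sim.config
        s = summarize_tds(pipeline200.calls, len(pipeline200.passing))
        n = len(pipeline200.passing)
        ci = 1.96 * np.sqrt(cfg.td_probability * (1 - cfg.td_probability) / n)
        assert abs(s["td_rate"] - cfg.td_probability) <= ci + 0.01

    def test_side_ratio_on_printed_design(self):
        """127 3'-only vs 58 5'-only events give the 2.2x ratio."""
        calls = []
        for k in range(127):
            calls.append(TransductionCall(f"t{k}", "3p", "ACGT" * 5, (0, 20)))
        for k in range(58):
            calls.append(TransductionCall(f"f{k}", "5p", "ACGT" * 5, (0, 20)))
        s = summarize_tds(calls, 543)
        assert round(s["ratio_3p_to_5p"], 1) == 2.2

    def test_cargo_conservation(self, pipeline200):
        """5'TSD + cargo + body + cargo + poly-A + 3'TSD tile the insertion."""
        by_id = {r.id: r for r in pipeline200.passing}
        calls_by = _calls_by_id(pipeline200)
        for rec_id, calls in calls_by.items():
            s = pipeline200.structures_by_id[rec_id]
            rec = by_id[rec_id]
            cuts = set()
            for c in calls:
                cuts.update(c.cargo_interval)
                assert rec.sequence[c.cargo_interval[0] : c.cargo_interval[1]] == c.cargo
            polya = s.regions.get("polya")
            if polya:
                assert polya[1] == len(rec.sequence)
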