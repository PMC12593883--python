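"""Synthetic-data generator: determinism, self-consistency, planted rates."""

import filecmp

import numpy as np
import pytest

from svatrx.simulate import SimulationConfig, simulate, simulate_reference, write_outputs


def test_identical_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=7, n_insertions=25)
    a = simulate(cfg)
    b = simulate(cfg)
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    write_outputs(a, dir_a)
    write_outputs(b, dir_b)
    for path_a in sorted(dir_a.iterdir()):
        assert filecmp.cmp(path_a, dir_b / path_a.name, shallow=False), path_a.name


def test_different_seeds_differ():
    a = simulate(SimulationConfig(seed=1, n_insertions=20))
    b = simulate(SimulationConfig(seed=2, n_insertions=20))
    assert a.records[0].sequence != b.records[0].sequence


def test_planted_reference_sva_count_matches_config():
    cfg = SimulationConfig(seed=3, n_insertions=20)
    ref = simulate_reference(cfg)
    assert len(ref.annotation.features["reference_sva"]) == cfg.n_reference_sva
    assert len(ref.annotation.features["alt_sva"]) == cfg.n_alt_sources


def test_planted_gene_fraction_near_target():
    cfg = SimulationConfig(seed=3)
    ref = simulate_reference(cfg)
    genic = sum(f.end - f.start for f in ref.annotation.features["genes"])
    total = sum(len(s) for s in ref.sequences.values())
    assert genic / total == pytest.approx(cfg.gene_fraction, abs=0.02)


def test_config_validation_rejects_bad_partitions():
    with pytest.raises(ValueError):
        SimulationConfig(truncation_split=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(td_probability=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_sources=2, n_alt_sources=2, n_nonref_sources=2)


def test_chromosome_too_short_for_features_is_error():
    with pytest.raises(ValueError, match="short"):
        simulate_reference(SimulationConfig(chromosome_length=5000))


def test_td_probability_zero_plants_no_transductions():
    res = simulate(
        SimulationConfig(seed=4, n_insertions=25, td_probability=0.0, orphan_td_count=0)
    )
    assert not res.truth.insertions.td5.any()
    assert not res.truth.insertions.td3.any()
    assert all(not d["td_segments"] for d in res.truth.details.values())


def test_singleton_has_one_heterozygote_among_unrelated(cohort200):
    truth = cohort200.truth.insertions
    singles = truth[truth.allele_count == 1]
    assert len(singles) > 20
    by_id = {r.id: r for r in cohort200.records}
    for rec_id in singles.id:
        gts = by_id[rec_id].genotypes
        carriers = [s for s in cohort200.samples if gts[s] == "0/1"]
        homs = [s for s in cohort200.samples if gts[s] == "1/1"]
        assert len(carriers) == 1 and not homs


def test_empirical_af_equals_truth_af(cohort200):
    by_id = {r.id: r for r in cohort200.records}
    for row in cohort200.truth.insertions.itertuples():
        if row.missing_samples:
            continue
        gts = by_id[row.id].genotypes
        count = sum(gts[s].count("1") for s in cohort200.samples)
        assert count / (2 * len(cohort200.samples)) == row.af


def test_trio_offspring_genotypes_mendelian(cohort200):
    for rec in cohort200.records:
        for child, (p1, p2) in cohort200.pedigree.items():
            child_gt = rec.genotypes[child]
            alleles = sorted(int(a) for a in child_gt.split("/"))
            possible = set()
            for a1 in {"0/0": (0,), "0/1": (0, 1), "1/1": (1,)}.get(rec.genotypes[p1], (0, 1)):
                for a2 in {"0/0": (0,), "0/1": (0, 1), "1/1": (1,)}.get(rec.genotypes[p2], (0, 1)):
                    possible.add(tuple(sorted((a1, a2))))
            assert tuple(alleles) in possible


def test_td_cargo_reconstructable_from_reference(cohort200):
    """Self-consistency: every emitted cargo equals its reference origin."""
    by_id = {r.id: r for r in cohort200.records}
    n_segments = 0
    for rec_id, detail in cohort200.truth.details.items():
        rec = by_id[rec_id]
        for seg in detail["td_segments"]:
            emitted = rec.sequence[seg["cargo_start"] : seg["cargo_end"]]
            assert emitted == cohort200.reference[seg["chrom"]][seg["start"] : seg["end"]]
            n_segments += 1
    assert n_segments > 50


def test_hotspot_truncation_geometry(cohort200, library):
    """A hotspot body ends exactly 233/323 bp upstream of the signal end and
    carries its cryptic signal at the stated offset."""
    truth = cohort200.truth.insertions
    by_id = {r.id: r for r in cohort200.records}
    checked = 0
    for row in truth[truth.hotspot.isin(["H233", "H323"])].itertuples():
        rec = by_id[row.id]
        cons = library[row.subfamily]
        sr = cons.region_seq("sine_r")
        offset = 233 if row.hotspot == "H233" else 323
        assert row.trunc3_offset == offset
        body = rec.sequence[int(row.body_start) : int(row.body_end)]
        expected_tail_of_body = sr[: len(sr) - offset]
        motif, motif_off = (("ATTAAA", 23) if row.hotspot == "H233" else ("AAGAAA", 17))
        if row.hotspot == "H233":
            edited = list(expected_tail_of_body)
            edited[len(sr) - offset - motif_off] = "A"
            expected_tail_of_body = "".join(edited)
        assert body.endswith(expected_tail_of_body)
        cut = len(body)
        assert body[cut - motif_off : cut - motif_off + 6] == motif
        checked += 1
    assert checked >= 3


def test_orphan_record_has_no_sva_body(cohort200):
    truth = cohort200.truth.insertions
    orphans = truth[truth.role == "orphan"]
    assert len(orphans) == cohort200.config.orphan_td_count
    for row in orphans.itertuples():
        assert row.body_start == row.body_end
        assert cohort200.truth.details[row.id]["td_segments"]
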