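"""Allele frequencies, chi-square goodness of fit and cohort summaries."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from svatrx.stats import (
    cohort_summaries,
    compute_af,
    expected_counts_by_length,
    gof_chisquare,
    per_individual_counts,
)


def _genotypes(n_samples=32, het=1, hom=0, missing=0):
    gts = {}
    k = 0
    for i in range(n_samples):
        s = f"S{i:02d}"
        if i < het:
            gts[s] = "0/1"
        elif i < het + hom:
            gts[s] = "1/1"
        elif missing and k < missing and i >= het + hom:
            gts[s] = "./."
            k += 1
        else:
            gts[s] = "0/0"
    return gts


class TestAlleleFrequency:
    def test_single_heterozygote_among_32(self):
        afs = compute_af({"x": _genotypes(het=1)})
        assert afs[0].af == 0.015625
        assert afs[0].singleton

    def test_all_homozygous_alt(self):
        afs = compute_af({"x": {f"S{i}": "1/1" for i in range(32)}})
        assert afs[0].af == 1.0

    def test_twenty_alt_alleles_of_64(self):
        afs = compute_af({"x": _genotypes(het=2, hom=9)})
        assert afs[0].alt_count == 20
        assert afs[0].af == 0.3125

    def test_excluded_samples_never_enter_denominator(self):
        gts = _genotypes(het=1)
        gts["T01"] = "1/1"
        afs = compute_af({"x": gts}, excluded_samples=["T01"])
        assert afs[0].n_alleles == 64
        assert afs[0].af == 0.015625

    def test_missing_genotypes_flagged(self):
        afs = compute_af({"x": _genotypes(het=2, missing=1)})
        assert not afs[0].complete
        assert len(afs[0].missing_samples) == 1

    def test_all_missing_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            afs = compute_af({"x": {f"S{i}": "./." for i in range(4)}})
        assert afs == []

    @given(st.integers(0, 6), st.integers(0, 4))
    def test_invariant_to_sample_order(self, het, hom):
        gts = _genotypes(het=het, hom=hom)
        shuffled = dict(reversed(list(gts.items())))
        a = compute_af({"x": gts})[0]
        b = compute_af({"x": shuffled})[0]
        assert (a.alt_count, a.n_alleles) == (b.alt_count, b.n_alleles)


class TestGoodnessOfFit:
    def test_exact_proportional_counts_give_zero(self):
        res = gof_chisquare([41, 59], [0.41, 0.59])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_expected_zero_is_error(self):
        with pytest.raises(ValueError):
            gof_chisquare([10, 10], [1.0, 0.0])

    def test_low_expected_warns(self):
        with pytest.warns(UserWarning, match="< 5"):
            gof_chisquare([3, 5], [0.5, 0.5])

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            gof_chisquare([10, 10], [0.6, 0.6])

    @given(
        st.lists(st.integers(1, 500), min_size=2, max_size=8),
        st.lists(st.integers(1, 20), min_size=2, max_size=8),
    )
    def test_matches_rational_arithmetic(self, observed, weights):
        """X^2 equals a Fraction-based direct computation on integer inputs."""
        k = min(len(observed), len(weights))
        observed, weights = observed[:k], weights[:k]
        total_w = sum(weights)
        props = [w / total_w for w in weights]
        props[-1] = 1.0 - sum(props[:-1])
        res = gof_chisquare(observed, props)
        total = sum(observed)
        exact = sum(
            (Fraction(o) - Fraction(w, total_w) * total) ** 2 / (Fraction(w, total_w) * total)
            for o, w in zip(observed, weights)
        )
        assert res.statistic == pytest.approx(float(exact), rel=1e-9)
        assert res.df == k - 1

    def test_expected_counts_by_length(self):
        assert expected_counts_by_length([5, 5], 100).tolist() == [50, 50]
        assert expected_counts_by_length([3, 1], 8).tolist() == [6, 2]
        with pytest.raises(ValueError):
            expected_counts_by_length([3, 0], 8)

    def test_null_rejection_rate_near_nominal(self):
        """Uniform-by-length counts accept the null in >= 93% of replicates."""
        rng = np.random.default_rng(2024)
        lengths = np.array([230e6, 190e6, 150e6, 120e6, 90e6])
        props = lengths / lengths.sum()
        n = 543
        accepted = 0
        for _ in range(100):
            observed = rng.multinomial(n, props)
            res = gof_chisquare(observed, props)
            accepted += res.p_value > 0.05
        assert accepted >= 93


class TestCohortSummaries:
    def test_all_singletons_fraction_one(self):
        gmap = {f"x{i}": _genotypes(het=1) for i in range(10)}
        afs = compute_af(gmap)
        out = cohort_summaries(afs)
        assert out["summary"]["singleton_fraction"] == 1.0

    def test_af_threshold_fraction_exact_by_construction(self, cohort200):
        afs = compute_af(cohort200.records, cohort200.pedigree)
        truth = cohort200.truth.insertions
        planted = truth[truth.missing_samples.fillna("") == ""]
        expected = (planted.af < 0.05).mean()
        out = cohort_summaries(afs)
        got = out["summary"]["af_below_threshold_fraction"]
        assert got == pytest.approx(expected, abs=0.02)

    def test_per_individual_counts_match_truth(self, cohort200):
        counts = per_individual_counts(cohort200.records, cohort200.pedigree)
        by_id = {r.id: r for r in cohort200.records}
        for row in counts.itertuples():
            expected = sum(
                1 for r in cohort200.records if "1" in r.genotypes[row.sample]
            )
            assert row.n_insertions == expected
        assert set(counts["sample"]) == set(cohort200.samples)

    def test_spectrum_total_matches_complete_insertions(self, cohort200):
        afs = compute_af(cohort200.records, cohort200.pedigree)
        out = cohort_summaries(afs)
        assert len(out["af_table"]) == sum(a.complete for a in afs)
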