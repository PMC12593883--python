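"""Allele frequencies, goodness-of-fit tests and cohort summaries.

Allele frequency of an insertion is its alternate allele count divided by
the total allele count (2 x included diploid samples); trio offspring are
excluded from the denominator.  Chi-square goodness-of-fit tests compare
observed counts against expected proportions (e.g. chromosome lengths as a
fraction of the genome, or the genomic fraction of protein-coding
sequence).  Group comparisons (ANOVA, Tukey HSD, t-tests) are delegated to
scipy/statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import InsertionRecord


@dataclass
class AlleleFrequency:
    insertion_id: str
    alt_count: int
    n_alleles: int
    af: float
    missing_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.af <= 1:
            raise ValueError("allele frequency outside [0, 1]")

    @property
    def singleton(self) -> bool:
        return self.alt_count == 1

    @property
    def complete(self) -> bool:
        return not self.missing_samples


@dataclass
class GofResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("X^2 must be non-negative")
        if abs(self.expected.sum() - self.observed.sum()) > 1e-9:
            raise ValueError("expected counts must sum to the observed total")


def compute_af(
    genotypes: Mapping[str, Mapping[str, str]] | Sequence[InsertionRecord],
    excluded_samples: Iterable[str] = (),
) -> list[AlleleFrequency]:
    """Per-insertion allele frequencies over the included samples.

    ``genotypes`` is either a mapping insertion id -> sample -> GT or a list
    of records.  Samples in ``excluded_samples`` (trio offspring) never
    enter the denominator; insertions with missing genotypes among included
    samples are flagged via ``missing_samples`` (their AF is computed over
    the full included denominator, with missing alleles counted as absent,
    and cohort tables should filter on ``complete``).
    """
    excluded = set(excluded_samples)
    if not isinstance(genotypes, Mapping):
        genotypes = {r.id: r.genotypes for r in genotypes}
    out = []
    for insertion_id in genotypes:
        gts = genotypes[insertion_id]
        included = [s for s in gts if s not in excluded]
        missing = [s for s in included if gts[s] == "./."]
        if len(missing) == len(included):
            warnings.warn(f"{insertion_id}: all genotypes missing; excluded from AF")
            continue
        alt = sum(gts[s].count("1") for s in included if gts[s] != "./.")
        n = 2 * len(included)
        out.append(
            AlleleFrequency(
                insertion_id=insertion_id,
                alt_count=alt,
                n_alleles=n,
                af=alt / n,
                missing_samples=missing,
            )
        )
    return out


def gof_chisquare(
    observed: Sequence[float], expected_proportions: Sequence[float]
) -> GofResult:
    """Chi-square goodness of fit of observed counts against proportions.

    X^2 = sum (O_i - E_i)^2 / E_i with E_i = p_i * sum(O); the p-value is
    the upper tail of the chi-square distribution with k - 1 degrees of
    freedom.  Expected counts of zero are an error; expected counts below 5
    trigger a validity warning.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.ndim != 1 or obs.shape != props.shape:
        raise ValueError("observed and proportions must be 1-D and equally long")
    if (obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    expected = props * obs.sum()
    if (expected == 0).any():
        raise ValueError("expected count of zero")
    if (expected < 5).any():
        warnings.warn("expected counts < 5: chi-square approximation may be poor")
    statistic, p_value = sps.chisquare(obs, f_exp=expected)
    return GofResult(
        statistic=float(statistic),
        df=len(obs) - 1,
        p_value=float(p_value),
        observed=obs,
        expected=expected,
    )


def expected_counts_by_length(
    chrom_lengths: Sequence[float] | Mapping[str, int], total_n: float
) -> np.ndarray:
    """Expected insertion counts proportional to chromosome length."""
    if isinstance(chrom_lengths, Mapping):
        lengths = np.array([chrom_lengths[c] for c in chrom_lengths], dtype=float)
    else:
        lengths = np.asarray(chrom_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return total_n * lengths / lengths.sum()


# ---------------------------------------------------------------------------
# delegated group comparisons


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(values: Sequence[float], labels: Sequence[str]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(labels))
    return pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])


def ttest_ind(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort summaries


def per_individual_counts(
    records: Sequence[InsertionRecord],
    excluded_samples: Iterable[str] = (),
    sample_metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Insertions carried per individual (loci with at least one allele)."""
    excluded = set(excluded_samples)
    samples = sorted(
        {s for r in records for s in r.genotypes if s not in excluded}
    )
    rows = []
    for sample in samples:
        n = sum(1 for r in records if "1" in r.genotypes.get(sample, ""))
        rows.append({"sample": sample, "n_insertions": n})
    df = pd.DataFrame(rows)
    if sample_metadata is not None:
        df = df.merge(sample_metadata, on="sample", how="left")
    return df


def cohort_summaries(
    afs: Sequence[AlleleFrequency],
    records: Sequence[InsertionRecord] | None = None,
    subfamily_of: Mapping[str, str] | None = None,
    td_class_of: Mapping[str, str] | None = None,
    sample_metadata: pd.DataFrame | None = None,
    excluded_samples: Iterable[str] = (),
    af_threshold: float = 0.05,
) -> dict:
    """AF spectra, singleton fractions, per-individual counts and group tests."""
    complete = [a for a in afs if a.complete]
    af_table = pd.DataFrame(
        {
            "insertion_id": [a.insertion_id for a in complete],
            "alt_count": [a.alt_count for a in complete],
            "af": [a.af for a in complete],
            "singleton": [a.singleton for a in complete],
        }
    )
    if subfamily_of is not None:
        af_table["subfamily"] = [subfamily_of.get(i, "") for i in af_table.insertion_id]
    if td_class_of is not None:
        af_table["td_class"] = [td_class_of.get(i, "none") for i in af_table.insertion_id]

    out: dict = {"af_table": af_table}
    summary = {
        "n_with_complete_genotypes": len(complete),
        "n_flagged_missing": len(afs) - len(complete),
        "singleton_fraction": float(af_table.singleton.mean()) if len(af_table) else np.nan,
        "af_below_threshold_fraction": (
            float((af_table.af < af_threshold).mean()) if len(af_table) else np.nan
        ),
        "af_mean": float(af_table.af.mean()) if len(af_table) else np.nan,
        "af_median": float(af_table.af.median()) if len(af_table) else np.nan,
    }
    if records is not None:
        counts = per_individual_counts(records, excluded_samples, sample_metadata)
        out["per_individual"] = counts
        summary["insertions_per_individual_mean"] = float(counts.n_insertions.mean())
        summary["insertions_per_individual_range"] = (
            int(counts.n_insertions.min()),
            int(counts.n_insertions.max()),
        )
        if sample_metadata is not None and "superpopulation" in counts:
            groups = [
                g.n_insertions.to_numpy()
                for _, g in counts.groupby("superpopulation")
                if len(g) > 1
            ]
            if len(groups) > 1:
                f_stat, p = anova_oneway(groups)
                summary["superpopulation_anova"] = {"F": f_stat, "p": p}
    out["summary"] = summary
    return out
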