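"""Cohort allele frequencies contrasted with reference populations.

Each variant's cohort alternate-allele count is tested against a reference
population's count with a two-sided Fisher's exact test; the family of tests
is controlled with a Bonferroni-adjusted significance level. Reference
panels publish frequencies rather than counts, so integer counts are
recovered by rounding frequency x 2N — 1KGP-style frequencies are exact
rationals of allele counts, so rounding reconstructs them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, nan
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .variant_io import MISSING

# Above this total count the exact integer enumeration hands over to scipy's
# C implementation; both compute the same two-sided hypergeometric sum.
_EXACT_LIMIT = 500

KGP_SIZES: dict[str, int] = {
    "ALL": 2504, "AFR": 661, "EUR": 503, "EAS": 504, "AMR": 347,
}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleFrequency:
    """Alternate-allele count and frequency at one biallelic site.

    ``called_alleles`` is 2 x the number of fully-called genotypes; missing
    genotypes are excluded from both numerator and denominator. ``freq`` is
    None when every genotype is missing.
    """

    rsid: str | None
    alt_count: int
    called_alleles: int

    def __post_init__(self) -> None:
        if self.called_alleles % 2 != 0:
            raise ValueError("called_alleles must be even (diploid samples)")
        if not 0 <= self.alt_count <= self.called_alleles:
            raise ValueError("alt_count must lie in [0, called_alleles]")

    @property
    def freq(self) -> float | None:
        if self.called_alleles == 0:
            return None
        return self.alt_count / self.called_alleles


@dataclass
class PopulationFreqPanel:
    """Per-population alternate-allele frequencies with diploid sample sizes.

    ``populations`` maps name -> (rsid -> alt frequency, n diploid samples).
    """

    populations: dict[str, tuple[dict[str, float], int]]

    def __post_init__(self) -> None:
        for name, (freqs, n) in self.populations.items():
            if n <= 0:
                raise ValueError(f"population {name}: n_diploid must be > 0")
            bad = [r for r, f in freqs.items() if not 0.0 <= f <= 1.0]
            if bad:
                raise ValueError(f"population {name}: frequencies outside [0,1] at {bad[:3]}")

    @property
    def names(self) -> list[str]:
        return list(self.populations)

    def freq(self, population: str, rsid: str) -> float | None:
        freqs, _ = self.populations[population]
        return freqs.get(rsid)

    def n_diploid(self, population: str) -> int:
        return self.populations[population][1]


@dataclass(frozen=True)
class FisherComparison:
    """One cohort-vs-reference allele-count test."""

    rsid: str
    population: str
    table: tuple[int, int, int, int]  # cohort alt, cohort ref, reference alt, reference ref
    p: float
    alpha_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_adjusted


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def allele_frequency(codes: Sequence[int], rsid: str | None = None) -> AlleleFrequency:
    """Alternate-allele frequency from a genotype-code column.

    Codes are {0, 1, 2, MISSING}; missing samples drop out of both the alt
    count and the called-allele denominator. An all-missing column yields an
    undefined frequency (freq None), not an exception.
    """
    arr = np.asarray(codes)
    valid = arr != MISSING
    if not np.isin(arr[valid], (0, 1, 2)).all():
        raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
    return AlleleFrequency(
        rsid=rsid,
        alt_count=int(arr[valid].sum()),
        called_alleles=2 * int(valid.sum()),
    )


def reconstruct_reference_counts(freq: float, n_diploid: int) -> tuple[int, int]:
    """Integer (alt_count, ref_count) from a published frequency and diploid
    sample size: alt = round(freq x 2N), ref = 2N - alt."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must lie in [0,1]")
    if n_diploid <= 0:
        raise ValueError("n_diploid must be positive")
    total = 2 * n_diploid
    alt = int(np.floor(freq * total + 0.5))
    return alt, total - alt


def infer_allele_count(
    freq: float, max_diploid: int, decimals: int | None = None
) -> tuple[int, int]:
    """Recover (alt_count, called_alleles) from a printed frequency when the
    per-site denominator is unknown (per-site missingness makes it vary).

    Searches even denominators up to 2 x max_diploid for an integer count
    whose exact frequency reprints as the given value at its precision —
    published tables mix rounding and truncation, so both are accepted.
    Among matches the largest denominator wins (fewest assumed missing
    genotypes); if nothing reprints exactly, the closest fraction wins.
    ``decimals`` defaults to the printed value's own decimal count.
    """
    if decimals is None:
        decimals = next(
            d for d in range(1, 12) if abs(round(freq, d) - freq) < 1e-12
        )
    scale = 10 ** decimals
    target = int(np.floor(freq * scale + 0.5))
    best_match: tuple[int, int] | None = None
    fallback: tuple[float, int, int] | None = None
    for n_dip in range(1, max_diploid + 1):
        alleles = 2 * n_dip
        base = int(np.floor(freq * alleles))
        for count in (base, base + 1):
            if not 0 <= count <= alleles:
                continue
            exact = count / alleles
            rounded = int(np.floor(exact * scale + 0.5))
            truncated = int(np.floor(exact * scale + 1e-9))
            if target in (rounded, truncated):
                best_match = (count, alleles)  # later = larger denominator
            err = abs(exact - freq)
            if fallback is None or err < fallback[0] - 1e-15:
                fallback = (err, count, alleles)
    if best_match is not None:
        return best_match
    assert fallback is not None
    return fallback[1], fallback[2]


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _support_numerators(r1: int, r2: int, c1: int) -> tuple[int, tuple[int, ...]]:
    """Hypergeometric numerators C(r1,x)C(r2,c1-x) over the support of x,
    plus the support minimum. All integers are exact."""
    x_min = max(0, c1 - r2)
    x_max = min(r1, c1)
    return x_min, tuple(comb(r1, x) * comb(r2, c1 - x) for x in range(x_min, x_max + 1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    The p-value sums the probabilities of all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's. Small tables (total <= 500) use exact integer enumeration;
    larger tables use scipy's implementation of the same definition.
    Degenerate margins with a single admissible table give p = 1.0; the
    all-zero table and negative counts are rejected.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("cannot test an all-zero table")
    if n_total > _EXACT_LIMIT:
        return float(_scipy_stats.fisher_exact([[a, b], [c, d]])[1])
    r1, r2, c1 = a + b, c + d, a + c
    x_min, nums = _support_numerators(r1, r2, c1)
    n_obs = nums[a - x_min]
    included = sum(n for n in nums if n <= n_obs)
    return included / comb(n_total, c1)


# ---------------------------------------------------------------------------
# Cohort-vs-reference comparison
# ---------------------------------------------------------------------------

def compare_to_reference(
    cohort: Iterable[AlleleFrequency],
    panel: PopulationFreqPanel,
    alpha: float = 0.05,
    family: str = "per-population",
    m: int | None = None,
) -> tuple[list[FisherComparison], dict[str, int]]:
    """Fisher's exact tests of cohort vs reference allele counts.

    One test per (variant, population) pair where the variant has a
    frequency in that population; variants absent from a population are
    skipped for it (no zero-frequency imputation). The Bonferroni family
    size is, by default, the number of variants tested against each
    population (``family="per-population"``); ``family="global"`` uses the
    total number of tests across populations; an explicit ``m`` overrides
    both. Returns the comparisons plus per-population counts of significant
    variants.
    """
    if family not in ("per-population", "global"):
        raise ValueError(f"unknown family {family!r}")
    cohort_list = [af for af in cohort if af.freq is not None]
    by_pop: dict[str, list[AlleleFrequency]] = {}
    for pop in panel.names:
        tested = [af for af in cohort_list
                  if af.rsid is not None and panel.freq(pop, af.rsid) is not None]
        if not tested:
            raise ValueError(f"no shared variants with population {pop!r}")
        by_pop[pop] = tested

    total_tests = sum(len(v) for v in by_pop.values())
    results: list[FisherComparison] = []
    counts: dict[str, int] = {}
    for pop, tested in by_pop.items():
        if m is not None:
            m_eff = m
        elif family == "per-population":
            m_eff = len(tested)
        else:
            m_eff = total_tests
        threshold = alpha / m_eff
        n_sig = 0
        for af in tested:
            ref_alt, ref_ref = reconstruct_reference_counts(
                panel.freq(pop, af.rsid), panel.n_diploid(pop)
            )
            table = (
                af.alt_count,
                af.called_alleles - af.alt_count,
                ref_alt,
                ref_ref,
            )
            if sum(table) == 0:
                continue
            p = fisher_exact_2x2(*table)
            cmp_ = FisherComparison(af.rsid, pop, table, p, threshold)
            results.append(cmp_)
            n_sig += cmp_.significant
        counts[pop] = n_sig
    return results, counts


def reproduce_significance_flags(
    fixture: pd.DataFrame,
    families: Sequence[int] = (2174, 2174 * 5),
    alpha: float = 0.05,
    max_diploid: int = 258,
    kgp_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Re-derive printed per-cell significance stars from printed frequencies.

    For each (variant, population) cell of a result-table fixture carrying
    ``freq_<pop>``/``sig_<pop>`` columns, cohort counts are recovered from
    the printed cohort frequency (per-site denominator search), reference
    counts from the printed population frequency and the 1KGP group size,
    and a Fisher test is evaluated at the Bonferroni threshold alpha/m for
    each candidate family size m. A cell "reproduces" when some candidate
    family predicts the printed star status. Every cell is reported.
    """
    sizes = dict(KGP_SIZES if kgp_sizes is None else kgp_sizes)
    pops = [c.removeprefix("freq_").upper() for c in fixture.columns
            if c.startswith("freq_") and c != "freq_crwgs"]
    rows = []
    for row in fixture.itertuples():
        alt, alleles = infer_allele_count(float(row.freq_crwgs), max_diploid)
        for pop in pops:
            ref_freq = getattr(row, f"freq_{pop.lower()}")
            if pd.isna(ref_freq):
                continue
            observed = bool(getattr(row, f"sig_{pop.lower()}"))
            ref_alt, ref_ref = reconstruct_reference_counts(
                float(ref_freq), sizes[pop]
            )
            p = fisher_exact_2x2(alt, alleles - alt, ref_alt, ref_ref)
            predictions = {m: p < alpha / m for m in families}
            rows.append({
                "rsid": row.rsid,
                "population": pop,
                "p": p,
                "observed_star": observed,
                **{f"predicted_m{m}": v for m, v in predictions.items()},
                "reproduced": any(v == observed for v in predictions.values()),
            })
    return pd.DataFrame(rows)
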