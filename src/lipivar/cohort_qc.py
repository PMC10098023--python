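"""Per-sample and cohort-level variant-calling QC metrics.

Ti/Tv and Het/non-ref-Hom are computed per sample over the variant sites the
sample actually carries (>= 1 alternate allele), either exome-wide or per
chromosome, optionally restricted to dbSNP-known sites (those with an rsID).
Cohort-level checks: a Welch t-test between two cohorts' per-sample metric
vectors, and a linear concordance model between observed and previously
reported allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import GenotypeMatrix


@dataclass(frozen=True)
class SampleQC:
    """QC counts for one sample within one scope (exome or a chromosome).

    ``titv`` / ``het_hom`` are None when their denominator is zero
    (undefined, not an error).
    """

    sample_id: str
    grouping: str
    n_snv: int
    n_indel: int
    n_het: int
    n_hom_alt: int
    n_transitions: int
    n_transversions: int

    @property
    def titv(self) -> float | None:
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions

    @property
    def het_hom(self) -> float | None:
        if self.n_hom_alt == 0:
            return None
        return self.n_het / self.n_hom_alt


def sample_qc(
    matrix: GenotypeMatrix,
    scope: str = "exome",
    known_only: bool = False,
) -> list[SampleQC]:
    """Per-sample carried-variant counts and ratios.

    A sample "carries" a site when its code is 1 or 2; missing genotypes
    contribute nothing. Ti/Tv is computed over carried biallelic SNVs only
    (transitions: A<->G, C<->T). ``scope`` is "exome" (one row per sample)
    or "per-chromosome". Per-chromosome counts sum exactly to the exome-wide
    counts.
    """
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise ValueError("cannot compute QC on an empty genotype matrix")
    if scope not in ("exome", "per-chromosome"):
        raise ValueError(f"unknown scope {scope!r}")

    keep = np.ones(matrix.n_sites, dtype=bool)
    if known_only:
        keep = np.array([s.rsid is not None for s in matrix.sites])
    is_snv = np.array([s.is_snv for s in matrix.sites]) & keep
    is_ti = np.array([s.is_transition for s in matrix.sites]) & keep
    is_tv = is_snv & ~is_ti
    is_indel = np.array(
        [s.variant_class in ("indel", "mixed") for s in matrix.sites]
    ) & keep

    if scope == "exome":
        groups: list[tuple[str, np.ndarray]] = [("exome", keep)]
    else:
        chroms = np.array([s.chrom for s in matrix.sites])
        groups = [(c, keep & (chroms == c)) for c in dict.fromkeys(chroms)]

    carried = matrix.codes >= 1
    het = matrix.codes == 1
    hom = matrix.codes == 2
    out: list[SampleQC] = []
    for label, mask in groups:
        out.extend(
            SampleQC(
                sample_id=sid,
                grouping=label,
                n_snv=int((carried[i] & is_snv & mask).sum()),
                n_indel=int((carried[i] & is_indel & mask).sum()),
                n_het=int((het[i] & mask).sum()),
                n_hom_alt=int((hom[i] & mask).sum()),
                n_transitions=int((carried[i] & is_ti & mask).sum()),
                n_transversions=int((carried[i] & is_tv & mask).sum()),
            )
            for i, sid in enumerate(matrix.sample_ids)
        )
    return out


def qc_frame(records: Iterable[SampleQC]) -> pd.DataFrame:
    """Tabular view of SampleQC records, one row per (sample, scope)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "grouping": r.grouping,
            "n_snv": r.n_snv,
            "n_indel": r.n_indel,
            "n_het": r.n_het,
            "n_hom_alt": r.n_hom_alt,
            "n_transitions": r.n_transitions,
            "n_transversions": r.n_transversions,
            "titv": r.titv if r.titv is not None else math.nan,
            "het_hom": r.het_hom if r.het_hom is not None else math.nan,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def compare_cohort_metrics(
    metrics_a: Sequence[float], metrics_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test between two cohorts'
    per-sample metric vectors. Returns (t, p).

    Degenerate zero-variance inputs are guarded: equal constant vectors give
    (0, 1); distinct constant vectors give (inf, 0).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least 2 samples for a t-test")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def frequency_concordance(
    observed: Mapping[str, float], reference: Mapping[str, float]
) -> tuple[float, float, float, float, int]:
    """Linear concordance between observed and previously reported allele
    frequencies at shared rsIDs.

    Returns (pearson r, p-value, slope, intercept, n shared). Requires at
    least 3 shared rsIDs.
    """
    shared = sorted(set(observed) & set(reference))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared rsids for a concordance model, got {len(shared)}"
        )
    x = np.array([reference[k] for k in shared], dtype=float)
    y = np.array([observed[k] for k in shared], dtype=float)
    fit = stats.linregress(x, y)
    return (
        float(fit.rvalue),
        float(fit.pvalue),
        float(fit.slope),
        float(fit.intercept),
        len(shared),
    )
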