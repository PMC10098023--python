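"""Ancestry screening on ancestry-informative markers (AIMs).

The in-scope slice of the ancestry workflow: extract AIM genotypes from one
or more labeled cohorts, keep only AIMs with complete genotypes across the
merged sample set, run PCA on the alternate-allele count matrix (pooled
centering, no variance scaling), and export per-population allele
frequencies for external tree/admixture software. Model-based admixture
inference itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix


@dataclass
class AIMMatrix:
    """Complete-case alternate-allele counts at AIMs for labeled samples."""

    sample_ids: list[str]
    population_labels: list[str]
    aim_rsids: list[str]
    counts: np.ndarray  # shape (n_samples, n_aims), codes {0,1,2}
    dropped_aims: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.aim_rsids)):
            raise ValueError("counts shape inconsistent with samples x aims")
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("AIM matrix must be complete-case with codes {0,1,2}")


def build_aim_matrix(
    cohorts: Sequence[tuple[GenotypeMatrix, str]],
    aim_rsids: Sequence[str],
) -> AIMMatrix:
    """Merge labeled cohorts over a requested AIM list.

    Keeps the intersection of the requested AIMs with the sites present in
    every cohort, then drops any AIM with a missing genotype anywhere in the
    merged sample set (complete-case rule); dropped AIMs are reported.
    Raises when no AIM survives.
    """
    if not aim_rsids:
        raise ValueError("AIM list must be non-empty")
    requested = list(dict.fromkeys(aim_rsids))
    per_cohort_cols: list[dict[str, np.ndarray]] = []
    for matrix, _ in cohorts:
        cols = {
            site.rsid: matrix.codes[:, j]
            for j, site in enumerate(matrix.sites)
            if site.rsid
        }
        per_cohort_cols.append(cols)
    shared = [
        rsid for rsid in requested
        if all(rsid in cols for cols in per_cohort_cols)
    ]
    if not shared:
        raise ValueError("no requested AIM is present in every cohort")

    sample_ids: list[str] = []
    labels: list[str] = []
    blocks = []
    for (matrix, label), cols in zip(cohorts, per_cohort_cols):
        sample_ids.extend(matrix.sample_ids)
        labels.extend([label] * matrix.n_samples)
        blocks.append(np.stack([cols[r] for r in shared], axis=1))
    counts = np.concatenate(blocks, axis=0)

    complete = ~(counts == MISSING).any(axis=0)
    kept = [r for r, ok in zip(shared, complete) if ok]
    dropped = [r for r, ok in zip(shared, complete) if not ok] + [
        r for r in requested if r not in shared
    ]
    if not kept:
        raise ValueError("every requested AIM has missing genotypes")
    return AIMMatrix(
        sample_ids=sample_ids,
        population_labels=labels,
        aim_rsids=kept,
        counts=counts[:, complete].astype(np.int8),
        dropped_aims=dropped,
    )


def pca_genotypes(
    matrix: AIMMatrix, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the alternate-allele count matrix.

    Columns are mean-centered (no unit-variance scaling) before the
    decomposition. Returns (coordinates, variance fractions); fractions are
    non-increasing, in [0,1], and sum to <= 1 (equality at k = rank). The
    sign of each component is fixed by forcing its largest-magnitude loading
    positive. A constant matrix yields all-zero coordinates, not an error.
    """
    n, p = matrix.counts.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 AIMs")
    if k < 1 or k > min(n, p):
        raise ValueError(f"k must lie in [1, {min(n, p)}]")
    x = matrix.counts.astype(float)
    x -= x.mean(axis=0)
    total_var = float((x ** 2).sum())
    if total_var == 0.0:
        return np.zeros((n, k)), np.zeros(k)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    fractions = (s[:k] ** 2) / total_var
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            coords[:, j] = -coords[:, j]
    return coords, fractions


def export_population_frequencies(
    matrix: AIMMatrix,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population alternate-allele frequencies at each AIM.

    frequency = alt copies / (2 x population size). ``grouping`` overrides
    the matrix's own population labels (sample id -> population). The output
    table (populations x AIMs) is suitable input for external tree or
    admixture software. Raises for an empty population.
    """
    if grouping is not None:
        labels = [grouping[s] for s in matrix.sample_ids]
    else:
        labels = matrix.population_labels
    df = pd.DataFrame(matrix.counts, columns=matrix.aim_rsids)
    df["population"] = labels
    sizes = df.groupby("population")["population"].count()
    if (sizes == 0).any():
        raise ValueError("every population needs at least one sample")
    freqs = df.groupby("population").sum(numeric_only=True)
    return freqs.div(2 * sizes, axis=0)
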