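"""Per-individual variant-burden profiles.

For each sample and variant class (VEP impact LOW/MODERATE/HIGH, the VOI
set, or any user-supplied partition) the profile counts sites carried
heterozygous, homozygous-alternate, and in total. Each variant belongs to
exactly one class (its most severe impact) so per-class totals add up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class BurdenProfile:
    """Carried-variant counts for one (sample, class) pair."""

    sample_id: str
    class_label: str
    n_het: int
    n_hom_alt: int

    @property
    def n_total(self) -> int:
        return self.n_het + self.n_hom_alt


def burden_per_sample(
    matrix: GenotypeMatrix,
    class_of: Mapping[str, str],
) -> list[BurdenProfile]:
    """Count het / hom-alt sites per sample within each variant class.

    ``class_of`` maps site keys (rsid or position fallback) to class labels;
    sites without a class are counted under an explicit "unclassified"
    bucket. Missing genotypes contribute nothing. Output order: samples in
    matrix order, classes in first-seen site order.
    """
    labels = [class_of.get(site.key, UNCLASSIFIED) for site in matrix.sites]
    classes = list(dict.fromkeys(labels))
    label_arr = np.array(labels)
    profiles: list[BurdenProfile] = []
    for i, sid in enumerate(matrix.sample_ids):
        het = matrix.codes[i] == 1
        hom = matrix.codes[i] == 2
        for cls in classes:
            mask = label_arr == cls
            profiles.append(
                BurdenProfile(
                    sample_id=sid,
                    class_label=cls,
                    n_het=int((het & mask).sum()),
                    n_hom_alt=int((hom & mask).sum()),
                )
            )
    return profiles


def cohort_burden_summary(
    profiles: Iterable[BurdenProfile],
    quantiles: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> pd.DataFrame:
    """Per-class means and distribution quantiles of burden across samples.

    Returns one row per class with mean_het, mean_hom_alt, mean_total (the
    first two sum exactly to the third) and total-count quantile columns.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one burden profile required")
    df = pd.DataFrame(
        {
            "class_label": [p.class_label for p in profiles],
            "n_het": [p.n_het for p in profiles],
            "n_hom_alt": [p.n_hom_alt for p in profiles],
            "n_total": [p.n_total for p in profiles],
        }
    )
    rows = []
    for cls, grp in df.groupby("class_label", sort=False):
        row = {
            "class_label": cls,
            "n_samples": len(grp),
            "mean_het": grp["n_het"].mean(),
            "mean_hom_alt": grp["n_hom_alt"].mean(),
            "mean_total": grp["n_total"].mean(),
        }
        for q in quantiles:
            row[f"q{int(q * 100)}"] = float(grp["n_total"].quantile(q))
        rows.append(row)
    return pd.DataFrame(rows)
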