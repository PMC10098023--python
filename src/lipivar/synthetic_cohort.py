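"""Synthetic diploid cohorts with the statistical structure the pipeline assumes.

The generator emulates a gene-panel resequencing cohort: site positions
uniform over the panel, alternate-allele frequencies from a rare-skewed beta
distribution, Hardy-Weinberg genotype sampling, a configurable
transition:transversion mix, indel/multiallelic fractions, independent
missingness, annotation scores on the scales the consensus filter consumes,
and reference-population panels derived from the cohort truth by logit-scale
perturbation plus an optional designed differential-frequency set.

One global seed drives independent per-stage substreams (sites, genotypes,
annotations, reference panel) so stages can be regenerated in isolation.
No linkage disequilibrium, demography or relatedness is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    MISSING,
    GenePanel,
    GenomicInterval,
    GenotypeMatrix,
    VariantSite,
    decompose_multiallelic,
    load_panel_gene_symbols,
)

# 1KGP phase-3 super-population diploid sample sizes.
from .popfreq_compare import KGP_SIZES  # noqa: E402

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(list("ACGT"))

LIPID_TRAIT_POOL = (
    "LDL cholesterol levels",
    "Familial hypertriglyceridemia",
    "Total cholesterol levels",
    "HDL cholesterol levels",
    "Hyperlipidemia, familial combined",
    "Apolipoprotein A1 levels",
)
NON_LIPID_TRAIT_POOL = (
    "Warfarin response",
    "Height",
    "Body mass index",
    "Type 2 diabetes",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the cohort the pipeline targets: 250 diploid samples over
    a ~5,000-site panel, site-level Ti/Tv odds of 2.0 (transcriptome-wide
    calling, below the ~3.0 coding-only standard), indel and multiallelic
    fractions of 5.4% and 2.9% of sites, rare-skewed Beta(0.3, 3) allele
    frequencies, 0.5% missing genotypes, and 98% of sites carrying an rsID.
    """

    n_samples: int = 250
    n_sites: int = 5000
    titv_target: float = 2.0
    indel_fraction: float = 0.054
    multiallelic_fraction: float = 0.029
    missing_rate: float = 0.005
    freq_model: tuple[str, float, float] = ("beta", 0.3, 3.0)
    risk_fraction: float = 0.02
    divergence: float = 0.5
    known_fraction: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_sites < 1:
            raise ValueError("n_samples and n_sites must be positive")
        if self.titv_target <= 0:
            raise ValueError("titv_target must be positive")
        for name in ("indel_fraction", "multiallelic_fraction", "risk_fraction",
                     "known_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0,1)")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")
        if self.freq_model[0] != "beta":
            raise ValueError(f"unsupported freq_model {self.freq_model[0]!r}")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent per-stage substream of the global seed."""
        stages = ("sites", "genotypes", "annotations", "reference")
        return np.random.default_rng([stages.index(stage), self.seed])


def default_panel(n_genes: int | None = None, gene_span: int = 8000,
                  flank: int = 300) -> GenePanel:
    """A synthetic stand-in panel: the packaged 69 lipid-gene symbols laid
    out as non-overlapping intervals across chromosomes 1-22."""
    symbols = load_panel_gene_symbols()
    if n_genes is not None:
        symbols = symbols[:n_genes]
    genes = []
    for i, symbol in enumerate(symbols):
        chrom = str(i % 22 + 1)
        start = 100_000 + (i // 22) * 1_000_000
        genes.append(
            (symbol, [GenomicInterval(chrom, start, start + gene_span - 1, symbol)])
        )
    return GenePanel(genes, flank=flank)


# ---------------------------------------------------------------------------
# Stage 1: sites
# ---------------------------------------------------------------------------

def simulate_sites(
    panel: GenePanel, cfg: SimulationConfig
) -> tuple[list[VariantSite], list[tuple[float, ...]]]:
    """Draw variant sites uniformly over the extended panel.

    Returns parent sites (possibly multiallelic) and per-site tuples of true
    alternate-allele frequencies, one per alt. Expected site-level Ti:Tv
    among SNVs equals ``cfg.titv_target``.
    """
    rng = cfg.rng("sites")
    intervals = panel.extended()
    lengths = np.array([len(iv) for iv in intervals])
    total = int(lengths.sum())
    if cfg.n_sites > total:
        raise ValueError(
            f"n_sites={cfg.n_sites} exceeds the {total} positions in the panel"
        )
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = rng.choice(total, size=cfg.n_sites, replace=False)
    flat.sort()

    a, b = cfg.freq_model[1], cfg.freq_model[2]
    p_ti = cfg.titv_target / (1.0 + cfg.titv_target)

    sites: list[VariantSite] = []
    freqs: list[tuple[float, ...]] = []
    for idx, fp in enumerate(flat):
        k = int(np.searchsorted(offsets, fp, side="right")) - 1
        iv = intervals[k]
        pos = iv.start + int(fp - offsets[k])
        is_indel = rng.random() < cfg.indel_fraction
        is_multi = rng.random() < cfg.multiallelic_fraction
        n_alts = 2 if is_multi else 1
        alts: list[str] = []
        if is_indel:
            anchor = str(rng.choice(_BASES))
            if rng.random() < 0.5:  # deletion site: ref spans two bases
                ref = anchor + str(rng.choice(_BASES))
                alts.append(anchor)
            else:  # insertion site
                ref = anchor
            while len(alts) < n_alts:
                alt = anchor + str(rng.choice(_BASES))
                if alt != ref and alt not in alts:
                    alts.append(alt)
        else:
            ref = str(rng.choice(_BASES))
            while len(alts) < n_alts:
                if rng.random() < p_ti:
                    alt = _TRANSITION_OF[ref]
                else:
                    alt = str(rng.choice([b for b in "ACGT"
                                          if b not in (ref, _TRANSITION_OF[ref])]))
                if alt not in alts:
                    alts.append(alt)
        rsid = f"rs9{idx:07d}" if rng.random() < cfg.known_fraction else None
        p_total = float(rng.beta(a, b))
        if n_alts == 1:
            site_freqs: tuple[float, ...] = (p_total,)
        else:
            w = rng.dirichlet(np.ones(n_alts))
            site_freqs = tuple(float(p_total * wi) for wi in w)
        sites.append(VariantSite(iv.chrom, pos, ref, tuple(alts), rsid))
        freqs.append(site_freqs)
    return sites, freqs


# ---------------------------------------------------------------------------
# Stage 2: genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    sites: Sequence[VariantSite],
    freqs: Sequence[tuple[float, ...]],
    cfg: SimulationConfig,
) -> GenotypeMatrix:
    """Hardy-Weinberg diploid sampling at the designed frequencies.

    Each sample draws two alleles i.i.d. per site (ref probability
    1 - sum(p_alt)); multiallelic parents are decomposed so the returned
    matrix is biallelic. Missingness is applied per (sample, parent site)
    independently of genotype.
    """
    rng = cfg.rng("genotypes")
    n = cfg.n_samples
    out_sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for site, p in zip(sites, freqs):
        probs = np.array([max(0.0, 1.0 - sum(p)), *p])
        probs = probs / probs.sum()
        alleles = rng.choice(len(probs), size=(n, 2), p=probs)
        miss = rng.random(n) < cfg.missing_rate
        pairs = [
            None if miss[i] else (int(alleles[i, 0]), int(alleles[i, 1]))
            for i in range(n)
        ]
        for child, codes in decompose_multiallelic(site, pairs):
            out_sites.append(child)
            columns.append(codes)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((n, 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, out_sites, codes)


# ---------------------------------------------------------------------------
# Stage 3: annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    sites: Sequence[VariantSite], cfg: SimulationConfig
):
    """Draw per-variant annotation records with a designed risk subset.

    A ``risk_fraction`` subset of variants receives >= 3 qualifying
    criteria among {SIFT < 0.05, PolyPhen2 in {P,D}, REVEL > 0.5,
    ClinPred > 0.5, lipid-related trait}; every other variant receives at
    most 2. Returns (records, truth) where truth maps each record key to its
    designed risk label — the parameter-recovery oracle for the consensus
    filter.
    """
    from .risk_prioritizer import AnnotationRecord

    if not sites:
        raise ValueError("sites must be non-empty")
    rng = cfg.rng("annotations")
    # annotate each unique variant key once (multiallelic children share
    # their parent's rsID and would otherwise collide in keyed joins)
    seen: set[str] = set()
    sites = [s for s in sites
             if not (s.key in seen or seen.add(s.key))]  # type: ignore[func-returns-value]
    n = len(sites)
    n_risk = int(round(cfg.risk_fraction * n))
    risk_idx = set(rng.choice(n, size=n_risk, replace=False).tolist())

    records: list = []
    truth: dict[str, bool] = {}
    criteria_names = ("sift", "polyphen", "revel", "clinpred", "phenotype")
    for i, site in enumerate(sites):
        is_risk = i in risk_idx
        n_crit = int(rng.integers(3, 6)) if is_risk else int(rng.integers(0, 3))
        on = set(rng.choice(5, size=n_crit, replace=False).tolist())
        flags = {name: (j in on) for j, name in enumerate(criteria_names)}
        sift = float(rng.uniform(0.0, 0.049)) if flags["sift"] \
            else float(rng.uniform(0.06, 1.0))
        polyphen = str(rng.choice(["P", "D"])) if flags["polyphen"] else "B"
        revel = float(rng.uniform(0.51, 1.0)) if flags["revel"] \
            else float(rng.uniform(0.0, 0.49))
        clinpred = float(rng.uniform(0.51, 1.0)) if flags["clinpred"] \
            else float(rng.uniform(0.0, 0.49))
        if flags["phenotype"]:
            traits = ((str(rng.choice(LIPID_TRAIT_POOL)), "risk factor"),)
        elif rng.random() < 0.3:
            traits = ((str(rng.choice(NON_LIPID_TRAIT_POOL)), "association"),)
        else:
            traits = ()
        rec = AnnotationRecord(
            rsid=site.rsid,
            gene=f"GENE_{site.chrom}",
            consequence_terms=("missense_variant",),
            sift_score=sift,
            polyphen_category=polyphen,
            revel=revel,
            clinpred=clinpred,
            clinvar_traits=traits,
            key=site.key,
        )
        records.append(rec)
        truth[site.key] = is_risk
    return records, truth


def simulate_decoy_annotations(n: int, seed: int = 0):
    """Missense decoy records satisfying at most two consensus criteria.

    Used to pad fixture-derived annotation sets so the consensus filter is
    exercised against non-qualifying variants. Returns (records, alt_counts)
    with alt counts >= 2 so rejection is driven by the evidence criteria,
    not the count threshold.
    """
    from .risk_prioritizer import AnnotationRecord

    rng = np.random.default_rng([9, seed])
    records = []
    alt_counts: dict[str, int] = {}
    criteria_names = ("sift", "polyphen", "revel", "clinpred", "phenotype")
    for i in range(n):
        key = f"decoy{i:04d}"
        n_crit = int(rng.integers(0, 3))
        on = set(rng.choice(5, size=n_crit, replace=False).tolist())
        flags = {name: (j in on) for j, name in enumerate(criteria_names)}
        records.append(
            AnnotationRecord(
                rsid=key,
                gene=f"DECOY{i % 7}",
                consequence_terms=("missense_variant",),
                sift_score=float(rng.uniform(0.0, 0.049)) if flags["sift"]
                else float(rng.uniform(0.06, 1.0)),
                polyphen_category="D" if flags["polyphen"] else "B",
                revel=float(rng.uniform(0.51, 1.0)) if flags["revel"]
                else float(rng.uniform(0.0, 0.49)),
                clinpred=float(rng.uniform(0.51, 1.0)) if flags["clinpred"]
                else float(rng.uniform(0.0, 0.49)),
                # decoy distractor traits avoid pharmacogenomic keywords so
                # the decoys also stay negative for the pharmaco route
                clinvar_traits=(
                    ((str(rng.choice(LIPID_TRAIT_POOL)), "risk factor"),)
                    if flags["phenotype"]
                    else ((str(rng.choice(("Height", "Body mass index",
                                           "Type 2 diabetes"))), "association"),)
                ),
            )
        )
        alt_counts[key] = int(rng.integers(2, 40))
    return records, alt_counts


# ---------------------------------------------------------------------------
# Stage 4: reference panel
# ---------------------------------------------------------------------------

def simulate_reference_panel(
    sites: Sequence[VariantSite],
    freqs: Sequence[float],
    cfg: SimulationConfig,
    populations: dict[str, int] | None = None,
    n_shifted: int = 0,
    shift: float = 0.3,
):
    """Build reference-population frequency panels from the cohort truth.

    Per population, frequencies are perturbed on the logit scale by
    N(0, divergence) noise and clipped to [0,1]; with divergence 0 the panel
    equals the cohort truth. A designated subset of ``n_shifted`` sites is
    additionally moved by ``shift`` on the probability scale (direction
    chosen to stay inside [0,1]) in every population — the designed
    differential set. Returns (PopulationFreqPanel, shifted-site keys).
    """
    from .popfreq_compare import PopulationFreqPanel

    if populations is None:
        populations = dict(KGP_SIZES)
    rng = cfg.rng("reference")
    keys = [s.key for s in sites]
    if len(set(keys)) != len(keys):
        raise ValueError(
            "duplicate site keys (multiallelic children sharing an rsID): "
            "per-rsID frequency panels are ambiguous there; simulate with "
            "multiallelic_fraction=0 for frequency-contrast experiments"
        )
    base = np.clip(np.asarray(freqs, dtype=float), 1e-6, 1 - 1e-6)

    shifted_idx = rng.choice(len(keys), size=n_shifted, replace=False) \
        if n_shifted else np.array([], dtype=int)
    shifted = np.zeros(len(keys), dtype=bool)
    shifted[shifted_idx] = True
    direction = np.where(base + shift <= 1.0, 1.0, -1.0)

    pops: dict[str, tuple[dict[str, float], int]] = {}
    for pop, n_dip in populations.items():
        p = base.copy()
        if cfg.divergence > 0:
            logit = np.log(p / (1 - p))
            logit += rng.normal(0.0, cfg.divergence, size=len(p))
            p = 1.0 / (1.0 + np.exp(-logit))
        p = np.where(shifted, np.clip(base + direction * shift, 0.0, 1.0), p)
        pops[pop] = (dict(zip(keys, p.astype(float))), int(n_dip))
    return PopulationFreqPanel(pops), [keys[i] for i in shifted_idx]


# ---------------------------------------------------------------------------
# Convenience bundle + writers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    panel: GenePanel
    sites: list[VariantSite]
    true_freqs: list[tuple[float, ...]]
    matrix: GenotypeMatrix
    annotations: list = field(default_factory=list)
    risk_truth: dict[str, bool] = field(default_factory=dict)


def simulate_cohort(
    cfg: SimulationConfig, panel: GenePanel | None = None
) -> SyntheticCohort:
    """Run the site, genotype and annotation stages under one config."""
    panel = panel if panel is not None else default_panel()
    sites, freqs = simulate_sites(panel, cfg)
    matrix = simulate_genotypes(sites, freqs, cfg)
    annotations, truth = simulate_annotations(matrix.sites, cfg)
    return SyntheticCohort(cfg, panel, sites, freqs, matrix, annotations, truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write VCF genotypes, an annotation TSV, and truth tables."""
    from .variant_io import write_cohort_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_vcf(out / "cohort.vcf", cohort.matrix)
    rows = [
        {
            "key": rec.key,
            "rsid": rec.rsid or "",
            "gene": rec.gene,
            "consequence_terms": ",".join(rec.consequence_terms),
            "sift_score": rec.sift_score,
            "polyphen_category": rec.polyphen_category,
            "revel": rec.revel,
            "clinpred": rec.clinpred,
            "clinvar_traits": "|".join(t for t, _ in rec.clinvar_traits),
        }
        for rec in cohort.annotations
    ]
    pd.DataFrame(rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        {"key": list(cohort.risk_truth), "is_risk": list(cohort.risk_truth.values())}
    )
    truth.to_csv(out / "risk_truth.tsv", sep="\t", index=False)
    site_rows = [
        {"key": s.key, "chrom": s.chrom, "pos": s.pos, "ref": s.ref,
         "alts": ",".join(s.alts), "true_freqs": ",".join(map(str, f))}
        for s, f in zip(cohort.sites, cohort.true_freqs)
    ]
    pd.DataFrame(site_rows).to_csv(out / "sites_truth.tsv", sep="\t", index=False)
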