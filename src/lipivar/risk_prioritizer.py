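"""Variant-of-interest selection.

Four routes nominate variants:

1. consensus risk — a missense variant qualifies when it satisfies at least
   ``min_sources`` of five evidence criteria (SIFT deleterious < 0.05,
   PolyPhen2 possibly/probably damaging, REVEL > 0.5, ClinPred > 0.5, a
   lipid-related ClinVar/GWAS phenotype) and carries more than one
   alternate-allele copy in the cohort;
2. high impact — most-severe VEP consequence maps to HIGH
   (stop gained, start lost, splice donor/acceptor, frameshift, ...);
3. pharmacogenomic/protective — ClinVar significance or trait strings
   indicating drug response or protection;
4. prior report — variants previously reported in Costa Rican / Latin
   American lipid studies (packaged curated list, user-replaceable).

The union, deduplicated by rsID (position+alleles as fallback for novel
variants), is the variant-of-interest (VOI) set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import VariantSite, load_paper_fixtures

# Sequence Ontology consequence -> VEP impact class (Ensembl severity
# ordering, embedded so results do not depend on a live service).
SO_IMPACT: dict[str, str] = {
    "transcript_ablation": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "stop_gained": "HIGH",
    "frameshift_variant": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "transcript_amplification": "HIGH",
    "feature_elongation": "HIGH",
    "feature_truncation": "HIGH",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "missense_variant": "MODERATE",
    "protein_altering_variant": "MODERATE",
    "splice_donor_5th_base_variant": "LOW",
    "splice_region_variant": "LOW",
    "splice_donor_region_variant": "LOW",
    "splice_polypyrimidine_tract_variant": "LOW",
    "incomplete_terminal_codon_variant": "LOW",
    "start_retained_variant": "LOW",
    "stop_retained_variant": "LOW",
    "synonymous_variant": "LOW",
    "coding_sequence_variant": "MODIFIER",
    "mature_miRNA_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "non_coding_transcript_exon_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "NMD_transcript_variant": "MODIFIER",
    "non_coding_transcript_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "TFBS_ablation": "MODIFIER",
    "TFBS_amplification": "MODIFIER",
    "TF_binding_site_variant": "MODIFIER",
    "regulatory_region_ablation": "MODIFIER",
    "regulatory_region_amplification": "MODIFIER",
    "regulatory_region_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "sequence_variant": "MODIFIER",
}

_IMPACT_SEVERITY = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

# Case-insensitive substrings marking a trait as lipid-related.
DEFAULT_LIPID_LEXICON: tuple[str, ...] = (
    "cholesterol",
    "triglycerid",
    "lipoprotein",
    "hyperlipid",
    "dyslipid",
    "hdl",
    "ldl",
    "sitosterolemia",
    "lcat",
    "apolipoprotein",
    "lipid metabolism",
    "lipid levels",
)

VALID_SIGNIFICANCE = frozenset({
    "protective", "drug response", "association", "risk factor",
    "likely pathogenic", "pathogenic", "benign", "uncertain", "conflicting",
})

_DRUG_RE = re.compile(r"response|statin|warfarin", re.IGNORECASE)
_PROTECT_RE = re.compile(r"protect|potection", re.IGNORECASE)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationRecord:
    """Aggregated functional annotation for one variant.

    ``clinvar_traits`` holds (trait string, significance category) pairs;
    ``gwas_traits`` holds bare trait strings. Scores may be absent (None).
    ``key`` is the dedup identity — the rsID when known, else a
    position+alleles string for novel variants.
    """

    rsid: str | None
    gene: str
    consequence_terms: tuple[str, ...] = ()
    sift_score: float | None = None
    sift_call: str | None = None
    polyphen_category: str | None = None
    revel: float | None = None
    clinpred: float | None = None
    clinvar_traits: tuple[tuple[str, str], ...] = ()
    gwas_traits: tuple[str, ...] = ()
    key: str = ""

    def __post_init__(self) -> None:
        for name in ("sift_score", "revel", "clinpred"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.sift_call not in (None, "deleterious", "tolerated"):
            raise ValueError(f"invalid sift_call {self.sift_call!r}")
        if self.polyphen_category not in (None, "B", "P", "D"):
            raise ValueError(f"invalid polyphen_category {self.polyphen_category!r}")
        for _, sig in self.clinvar_traits:
            if sig not in VALID_SIGNIFICANCE:
                raise ValueError(f"invalid significance category {sig!r}")
        if not self.key:
            if not self.rsid:
                raise ValueError("record needs an rsid or an explicit key")
            object.__setattr__(self, "key", self.rsid)

    @property
    def trait_strings(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.clinvar_traits) + self.gwas_traits


@dataclass(frozen=True)
class RiskCall:
    """Consensus-filter verdict for one variant."""

    key: str
    gene: str
    criteria: tuple[bool, bool, bool, bool, bool]  # sift, polyphen, revel, clinpred, phenotype
    alt_count: int
    min_sources: int = 3
    min_alt_count: int = 2

    @property
    def n_criteria(self) -> int:
        return sum(self.criteria)

    @property
    def qualifies(self) -> bool:
        return (
            self.n_criteria >= self.min_sources
            and self.alt_count >= self.min_alt_count
        )


@dataclass(frozen=True)
class VOIRecord:
    """One variant of interest with the route(s) that selected it."""

    key: str
    gene: str
    routes: frozenset[str]
    provenance: str  # first route that nominated it

    def __post_init__(self) -> None:
        if not self.routes:
            raise ValueError("a VOI record needs at least one route")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def impact_of(
    consequence_terms: Iterable[str], strict: bool = False
) -> str:
    """Most severe VEP impact class across a variant's consequence terms.

    Unknown terms map to MODIFIER with a warning (or raise under
    ``strict``). Order-invariant and idempotent.
    """
    best = "MODIFIER"
    seen = False
    for term in consequence_terms:
        seen = True
        if term not in SO_IMPACT:
            if strict:
                raise ValueError(f"unknown consequence term {term!r}")
            warnings.warn(f"unknown consequence term {term!r}; treating as MODIFIER")
            impact = "MODIFIER"
        else:
            impact = SO_IMPACT[term]
        if _IMPACT_SEVERITY[impact] > _IMPACT_SEVERITY[best]:
            best = impact
    if not seen:
        raise ValueError("at least one consequence term required")
    return best


def lipid_phenotype_match(
    traits: Iterable[str],
    lexicon: Sequence[str] = DEFAULT_LIPID_LEXICON,
) -> bool:
    """True iff any trait string contains a lexicon term (case-insensitive)."""
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    terms = [t.lower() for t in lexicon]
    return any(any(term in trait.lower() for term in terms) for trait in traits)


def consensus_filter(
    annotations: Iterable[AnnotationRecord],
    alt_counts: Mapping[str, int],
    min_sources: int = 3,
    min_alt_count: int = 2,
    lexicon: Sequence[str] = DEFAULT_LIPID_LEXICON,
) -> list[RiskCall]:
    """Score each annotated missense variant against the five evidence
    criteria and flag those meeting the consensus rule.

    Criteria: (1) SIFT deleterious (score < 0.05 or an explicit deleterious
    call), (2) PolyPhen2 P or D, (3) REVEL > 0.5, (4) ClinPred > 0.5,
    (5) a lipid-related ClinVar/GWAS phenotype. Missing scores count as
    criterion-false. Records whose consequence terms exclude
    ``missense_variant`` are skipped; records without consequence terms are
    assumed eligible. A variant qualifies with >= ``min_sources`` satisfied
    criteria and an alternate-allele count >= ``min_alt_count``.
    """
    calls: list[RiskCall] = []
    for rec in annotations:
        if rec.consequence_terms and "missense_variant" not in rec.consequence_terms:
            continue
        sift_ok = (
            (rec.sift_score is not None and rec.sift_score < 0.05)
            or rec.sift_call == "deleterious"
        )
        polyphen_ok = rec.polyphen_category in ("P", "D")
        revel_ok = rec.revel is not None and rec.revel > 0.5
        clinpred_ok = rec.clinpred is not None and rec.clinpred > 0.5
        pheno_ok = lipid_phenotype_match(rec.trait_strings, lexicon)
        calls.append(
            RiskCall(
                key=rec.key,
                gene=rec.gene,
                criteria=(sift_ok, polyphen_ok, revel_ok, clinpred_ok, pheno_ok),
                alt_count=int(alt_counts.get(rec.key, 0)),
                min_sources=min_sources,
                min_alt_count=min_alt_count,
            )
        )
    return calls


def pharmaco_protective_flags(
    annotations: Iterable[AnnotationRecord],
) -> dict[str, str]:
    """Classify each variant as drug_response / protective / both / none
    from its ClinVar significance categories and trait strings."""
    out: dict[str, str] = {}
    for rec in annotations:
        drug = any(sig == "drug response" for _, sig in rec.clinvar_traits)
        protective = any(sig == "protective" for _, sig in rec.clinvar_traits)
        for trait in rec.trait_strings:
            if _PROTECT_RE.search(trait):
                protective = True
            elif _DRUG_RE.search(trait):
                drug = True
        if drug and protective:
            out[rec.key] = "both"
        elif drug:
            out[rec.key] = "drug_response"
        elif protective:
            out[rec.key] = "protective"
        else:
            out[rec.key] = "none"
    return out


def load_prior_report_list() -> list[tuple[str, str]]:
    """The packaged curated (rsid, source) list of variants previously
    reported in Costa Rican / Latin American lipid studies."""
    df = load_paper_fixtures("table6")
    return list(zip(df["rsid"], df["source"]))


def prior_report_match(
    cohort: Iterable[str | VariantSite],
    curated: Sequence[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Intersect cohort variants with a curated prior-report list by rsID.

    ``cohort`` holds rsID strings or VariantSite objects. Duplicates in the
    cohort collapse to a single match. Returns (rsid, source) pairs in
    curated-list order.
    """
    if curated is None:
        curated = load_prior_report_list()
    cohort_rsids = set()
    for item in cohort:
        rsid = item.rsid if isinstance(item, VariantSite) else item
        if rsid:
            cohort_rsids.add(rsid)
    return [(rsid, source) for rsid, source in curated if rsid in cohort_rsids]


def _normalize_route(items) -> list[tuple[str, str]]:
    """Accept keys, (key, gene) pairs, RiskCalls, or annotation-like objects."""
    out = []
    for item in items:
        if isinstance(item, str):
            out.append((item, ""))
        elif isinstance(item, RiskCall):
            out.append((item.key, item.gene))
        elif isinstance(item, tuple):
            out.append((item[0], item[1] if len(item) > 1 else ""))
        else:
            out.append((item.key, getattr(item, "gene", "")))
    return out


def assemble_voi(
    consensus,
    high_impact,
    pharmaco,
    prior_report,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> list[VOIRecord]:
    """Union the four selection routes into a deduplicated VOI table.

    Each argument is an iterable of variant keys, (key, gene) pairs, or
    RiskCall objects; a variant appearing on several routes yields a single
    record listing all of them, with provenance set to the first route that
    nominated it. Output is ordered by genomic position when a
    key -> (chrom, pos) mapping is supplied, else by first appearance.
    """
    routes_in = [
        ("consensus_risk", _normalize_route(consensus)),
        ("high_impact", _normalize_route(high_impact)),
        ("pharmaco_protective", _normalize_route(pharmaco)),
        ("prior_report", _normalize_route(prior_report)),
    ]
    merged: dict[str, dict] = {}
    for route_name, items in routes_in:
        for key, gene in items:
            if key not in merged:
                merged[key] = {"gene": gene, "routes": [], "provenance": route_name}
            if gene and not merged[key]["gene"]:
                merged[key]["gene"] = gene
            if route_name not in merged[key]["routes"]:
                merged[key]["routes"].append(route_name)
    records = [
        VOIRecord(key, info["gene"], frozenset(info["routes"]), info["provenance"])
        for key, info in merged.items()
    ]
    if positions is not None:
        records.sort(key=lambda r: positions.get(r.key, ("~", 0)))
    return records


# ---------------------------------------------------------------------------
# Fixture adapters
# ---------------------------------------------------------------------------

def records_from_consensus_fixture(df: pd.DataFrame) -> list[AnnotationRecord]:
    """Turn the packaged consensus-risk table (source flags S/P/R/C plus
    phenotype columns) into AnnotationRecords on the scales the filter
    consumes: S -> a deleterious SIFT call, P -> PolyPhen2 D, R -> REVEL
    0.9, C -> ClinPred 0.9; absent flags leave the score unset."""
    records = []
    for row in df.itertuples():
        sources = {s.strip() for s in str(row.sources).split(",")}
        clinvar = tuple(
            (t, "risk factor")
            for t in str(getattr(row, "clinvar_traits", "") or "").split("|") if t
        )
        gwas = tuple(
            t for col in ("gwas_traits", "teslovich_traits")
            for t in str(getattr(row, col, "") or "").split("|") if t
        )
        records.append(
            AnnotationRecord(
                rsid=row.rsid,
                gene=row.gene,
                consequence_terms=("missense_variant",),
                sift_call="deleterious" if "S" in sources else None,
                polyphen_category="D" if "P" in sources else None,
                revel=0.9 if "R" in sources else None,
                clinpred=0.9 if "C" in sources else None,
                clinvar_traits=clinvar,
                gwas_traits=gwas,
            )
        )
    return records


def records_from_pharmaco_fixture(df: pd.DataFrame) -> list[AnnotationRecord]:
    """AnnotationRecords for the packaged pharmacogenomic/protective table."""
    records = []
    for row in df.itertuples():
        clinvar = tuple(
            (t, "drug response" if _DRUG_RE.search(t) else
             "protective" if _PROTECT_RE.search(t) else "association")
            for t in str(getattr(row, "clinvar_traits", "") or "").split("|") if t
        )
        gwas = tuple(
            t for t in str(getattr(row, "gwas_traits", "") or "").split("|") if t
        )
        records.append(
            AnnotationRecord(
                rsid=row.rsid, gene=row.gene,
                clinvar_traits=clinvar, gwas_traits=gwas,
            )
        )
    return records
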