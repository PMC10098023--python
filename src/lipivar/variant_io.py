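"""Variant and panel I/O: the data model shared by the whole pipeline.

Coordinates are 1-based inclusive throughout (VCF convention). BED input is
converted on read. Genotypes are stored as alternate-allele dosage codes per
(sample, biallelic site): 0 hom-ref, 1 het, 2 hom-alt, and ``MISSING`` (-1)
for uncalled or half-called genotypes. Phasing is ignored — only dosage
matters downstream. Multiallelic records are decomposed into one biallelic
site per alternate allele before anything else sees them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING: int = -1

_VALID_BASES = frozenset("ACGT")

_FIXTURE_FILES = {
    "table2": "table2_variant_counts.tsv",
    "table3": "table3_high_impact.tsv",
    "table4": "table4_pharmaco.tsv",
    "table5": "table5_consensus_risk.tsv",
    "table6": "table6_prior_reports.tsv",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval, optionally labeled."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(end < start)"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GenePanel:
    """An ordered gene panel: (symbol, intervals) pairs plus a flank in bp.

    ``extended()`` returns the flank-extended, per-chromosome merged interval
    set actually used for subsetting. Neighbouring transcripts that overlap
    after extension are merged.
    """

    genes: list[tuple[str, list[GenomicInterval]]]
    flank: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be non-negative")
        symbols = [g for g, _ in self.genes]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in panel: {dupes}")

    @property
    def gene_symbols(self) -> list[str]:
        return [g for g, _ in self.genes]

    def extended(self) -> list[GenomicInterval]:
        all_ivs = [iv for _, ivs in self.genes for iv in ivs]
        return extend_and_merge_intervals(all_ivs, self.flank)

    def contains(self, chrom: str, pos: int) -> bool:
        chrom = chrom.removeprefix("chr")
        for iv in self.extended():
            if iv.chrom.removeprefix("chr") == chrom and iv.start <= pos <= iv.end:
                return True
        return False


@dataclass(frozen=True)
class VariantSite:
    """One called site. ``variant_class`` and ``allelism`` are derived from
    the alleles at construction time via :func:`classify_variant`."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    rsid: str | None = None
    variant_class: str = field(default="", compare=False)
    allelism: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        vclass, allelism = classify_variant(self.ref, self.alts)
        object.__setattr__(self, "variant_class", vclass)
        object.__setattr__(self, "allelism", allelism)

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def is_transition(self) -> bool:
        """True for A<->G / C<->T substitutions (biallelic SNVs only)."""
        if not (self.is_snv and len(self.alts) == 1):
            return False
        return {self.ref, self.alts[0]} in ({"A", "G"}, {"C", "T"})

    @property
    def key(self) -> str:
        """Dedup key: rsid when known, else position+alleles."""
        if self.rsid:
            return self.rsid
        return f"{self.chrom}:{self.pos}:{self.ref}:{','.join(self.alts)}"


@dataclass
class GenotypeMatrix:
    """samples x biallelic-sites matrix of alt-dosage codes {0,1,2,MISSING}."""

    sample_ids: list[str]
    sites: list[VariantSite]
    codes: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("sample ids must be unique")
        if self.codes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.codes[bad])}")
        for s in self.sites:
            if len(s.alts) != 1:
                raise ValueError(f"matrix sites must be biallelic, got {s}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j]


# ---------------------------------------------------------------------------
# Interval handling
# ---------------------------------------------------------------------------

def extend_and_merge_intervals(
    intervals: Iterable[GenomicInterval], flank: int = 0
) -> list[GenomicInterval]:
    """Grow each interval by ``flank`` bp on both sides (clipped at position
    1), then merge overlapping or book-ended intervals per chromosome.

    Output is sorted by (chrom, start). Idempotent at flank 0.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    grown = [
        GenomicInterval(iv.chrom, max(1, iv.start - flank), iv.end + flank, iv.label)
        for iv in intervals
    ]
    grown.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in grown:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, prev.label)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# Variant classification & decomposition
# ---------------------------------------------------------------------------

def classify_variant(ref: str, alts: Sequence[str]) -> tuple[str, str]:
    """Classify a site as (variant_class, allelism).

    SNV iff every allele has length 1; an alt whose length differs from the
    ref is an indel; a site mixing SNV and indel alts is ``mixed``. Only
    concrete ACGT alleles are supported — symbolic (``<DEL>``), breakend and
    ``*`` alleles raise.
    """
    if not alts:
        raise ValueError("at least one alternate allele required")
    for allele in (ref, *alts):
        if not allele or not _VALID_BASES.issuperset(allele):
            raise ValueError(f"unsupported allele {allele!r}: only A/C/G/T strings")
    for alt in alts:
        if alt == ref:
            raise ValueError(f"alt allele equals ref ({ref})")
    per_alt = [
        "SNV" if len(ref) == 1 and len(alt) == 1 else "indel" for alt in alts
    ]
    if all(c == "SNV" for c in per_alt):
        vclass = "SNV"
    elif all(c == "indel" for c in per_alt):
        vclass = "indel"
    else:
        vclass = "mixed"
    return vclass, ("biallelic" if len(alts) == 1 else "multiallelic")


def decompose_multiallelic(
    site: VariantSite, allele_pairs: Sequence[tuple[int, int] | None]
) -> list[tuple[VariantSite, np.ndarray]]:
    """Split a site into one biallelic child per alternate allele.

    ``allele_pairs`` holds per-sample diploid allele indices (0 = ref,
    k = k-th alt), or None for missing/half-called genotypes. Each child's
    code counts copies of that single alt; samples missing at the parent are
    missing in every child, so alt-allele copies are conserved.
    """
    children: list[tuple[VariantSite, np.ndarray]] = []
    for k, alt in enumerate(site.alts, start=1):
        codes = np.full(len(allele_pairs), MISSING, dtype=np.int8)
        for i, pair in enumerate(allele_pairs):
            if pair is not None:
                codes[i] = (pair[0] == k) + (pair[1] == k)
        child = VariantSite(site.chrom, site.pos, site.ref, (alt,), site.rsid)
        children.append((child, codes))
    return children


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _norm_chrom(chrom: str) -> str:
    return chrom.removeprefix("chr")


def read_cohort_vcf(
    path: str | Path,
    panel: GenePanel | None = None,
    keep_filtered: bool = False,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Read a multi-sample VCF into the internal model.

    Sites outside the (extended, merged) panel are dropped; multiallelic
    records are decomposed; rsIDs come from the ID column ("." -> None).
    Contig naming dialects ("chr1" vs "1") are reconciled by comparing
    prefix-stripped names. Records whose FILTER is set and not PASS are
    dropped unless ``keep_filtered``. Half-calls count as missing.
    """
    panel_ivs = None
    if panel is not None:
        panel_ivs = [
            GenomicInterval(_norm_chrom(iv.chrom), iv.start, iv.end, iv.label)
            for iv in panel.extended()
        ]

    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        sites: list[VariantSite] = []
        columns: list[np.ndarray] = []
        for rec in vcf:
            filters = set(rec.filter.keys())
            if filters and filters != {"PASS"} and not keep_filtered:
                continue
            if panel_ivs is not None:
                chrom = _norm_chrom(rec.chrom)
                if not any(iv.contains(chrom, rec.pos) for iv in panel_ivs):
                    continue
            alts = rec.alts or ()
            if not alts:
                continue
            try:
                parent = VariantSite(
                    rec.chrom, rec.pos, rec.ref, tuple(alts),
                    rsid=rec.id if rec.id and rec.id != "." else None,
                )
            except ValueError:  # symbolic/breakend alleles
                warnings.warn(
                    f"skipping unsupported alleles at {rec.chrom}:{rec.pos}"
                )
                continue
            pairs: list[tuple[int, int] | None] = []
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    pairs.append(None)
                else:
                    pairs.append((gt[0], gt[1]))
            for child, codes in decompose_multiallelic(parent, pairs):
                sites.append(child)
                columns.append(codes)

    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(samples, sites, codes)
    return sites, matrix


def write_cohort_vcf(path: str | Path, matrix: GenotypeMatrix) -> None:
    """Write a (biallelic) GenotypeMatrix as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
        header.contigs.add(chrom)
    for sample in matrix.sample_ids:
        header.add_sample(sample)
    order = sorted(
        range(matrix.n_sites),
        key=lambda j: (matrix.sites[j].chrom, matrix.sites[j].pos),
    )
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            site = matrix.sites[j]
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, site.alts[0]),
                id=site.rsid,
            )
            for i, sample in enumerate(matrix.sample_ids):
                rec.samples[sample]["GT"] = gt_of[int(matrix.codes[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# Panel / table readers
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, flank: int = 0) -> GenePanel:
    """Read a gene panel from BED (0-based half-open; 4th column = gene) or
    TSV with columns gene, chrom, start, end (1-based inclusive)."""
    path = Path(path)
    per_gene: dict[str, list[GenomicInterval]] = {}
    if path.suffix.lower() == ".bed":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            gene = fields[3] if len(fields) > 3 else chrom
            per_gene.setdefault(gene, []).append(
                GenomicInterval(chrom, start0 + 1, end0, gene)
            )
    else:
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples():
            per_gene.setdefault(row.gene, []).append(
                GenomicInterval(str(row.chrom), int(row.start), int(row.end), row.gene)
            )
    return GenePanel(list(per_gene.items()), flank=flank)


def read_reference_frequencies(path: str | Path):
    """Read a reference-population frequency TSV into a PopulationFreqPanel.

    Expected columns: rsid, population, alt_freq, n_diploid. Duplicate
    (rsid, population) rows and out-of-range frequencies are rejected.
    """
    from .popfreq_compare import PopulationFreqPanel

    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"{path}: empty reference frequency table")
        return PopulationFreqPanel({})
    dup = df.duplicated(subset=["rsid", "population"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["rsid", "population"]].tolist()
        raise ValueError(f"duplicate reference frequency entry for {tuple(key)}")
    if ((df["alt_freq"] < 0) | (df["alt_freq"] > 1)).any():
        bad = df.loc[(df["alt_freq"] < 0) | (df["alt_freq"] > 1), "rsid"].iloc[0]
        raise ValueError(f"allele frequency outside [0,1] at {bad}")
    populations: dict[str, tuple[dict[str, float], int]] = {}
    for pop, group in df.groupby("population", sort=False):
        n = int(group["n_diploid"].iloc[0])
        freqs = dict(zip(group["rsid"], group["alt_freq"].astype(float)))
        populations[str(pop)] = (freqs, n)
    return PopulationFreqPanel(populations)


def load_paper_fixtures(name: str) -> pd.DataFrame:
    """Load one of the packaged result-table transcriptions.

    Valid names: table2 (variant class counts), table3 (high-impact
    variants), table4 (pharmacogenomic/protective variants), table5
    (consensus risk variants), table6 (prior regional reports). '-' cells
    (no data in that population) are returned as NaN.
    """
    if name not in _FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURE_FILES)}"
        )
    ref = resources.files("lipivar.data") / _FIXTURE_FILES[name]
    with resources.as_file(ref) as fp:
        df = pd.read_csv(fp, sep="\t", na_values=["-"], keep_default_na=False)
    return df


def load_panel_gene_symbols() -> list[str]:
    """The 69 lipid-metabolism gene symbols of the packaged panel."""
    ref = resources.files("lipivar.data") / "lipid_panel_genes.txt"
    return [g for g in ref.read_text().split() if g]
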