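"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based closed (the VCF convention); BED's 0-based
half-open convention is applied only at the file boundary. Indel records are
parsed but flagged so the SNP-based statistics can exclude them. All readers
reject malformed input rather than silently coercing it, and every
writer/reader pair is inverse on valid data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
import skbio

logger = logging.getLogger(__name__)

GT_MISSING, GT_HOM_REF, GT_HET, GT_HOM_ALT = -1, 0, 1, 2
COUNT_UNKNOWN = -1


# ---------------------------------------------------------------------------
# VariantTable
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Per-sample genotype calls and allele depths at reference-anchored
    biallelic sites — the pipeline's universal currency.

    ``sites`` has columns chrom, pos (1-based), ref, alt (and ``is_indel``
    after reading from VCF); ``gt`` is a sites x samples int8 matrix coded
    -1 missing / 0 hom-ref / 1 het / 2 hom-alt (the code equals the
    alt-allele dosage); ``ad_ref``/``ad_alt`` hold allele depths with -1 for
    unknown.
    """

    sites: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        n = len(self.sites)
        for arr_name in ("gt", "ad_ref", "ad_alt"):
            arr = np.asarray(getattr(self, arr_name))
            if arr.size == 0:
                arr = arr.reshape(n, len(self.samples))
            elif arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape != (n, len(self.samples)):
                raise ValueError(f"{arr_name} shape {arr.shape} != ({n}, {len(self.samples)})")
            setattr(self, arr_name, arr)
        self.gt = self.gt.astype(np.int8)
        key = self.sites[["chrom", "pos"]].assign(alt=self.sites["alt"])
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, alt) sites")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def gt_for(self, sample: str) -> np.ndarray:
        return self.gt[:, self.sample_index(sample)]

    def counts_for(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.sample_index(sample)
        return self.ad_ref[:, j], self.ad_alt[:, j]

    def snp_mask(self) -> np.ndarray:
        """True at single-nucleotide sites (indels excluded)."""
        if "is_indel" in self.sites.columns:
            return ~self.sites["is_indel"].to_numpy()
        return (
            self.sites["ref"].str.len().to_numpy() == 1
        ) & (self.sites["alt"].str.len().to_numpy() == 1)

    def site_rows(self, chrom: str, start: int | None = None, end: int | None = None) -> np.ndarray:
        mask = (self.sites["chrom"] == chrom).to_numpy()
        pos = self.sites["pos"].to_numpy()
        if start is not None:
            mask &= pos >= start
        if end is not None:
            mask &= pos <= end
        return np.flatnonzero(mask)

    def subset_sites(self, rows: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.sites.iloc[rows],
            list(self.samples),
            self.gt[rows],
            self.ad_ref[rows],
            self.ad_alt[rows],
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True).equals(
                other.sites[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
            )
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.ad_ref, other.ad_ref)
            and np.array_equal(self.ad_alt, other.ad_alt)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(table: VariantTable, genome=None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if genome is not None:
        for chrom, length in genome.chromosomes:
            header.contigs.add(chrom, length=length)
    else:
        for chrom in pd.unique(table.sites["chrom"]):
            length = int(table.sites.loc[table.sites["chrom"] == chrom, "pos"].max()) + 1
            header.contigs.add(str(chrom), length=length)
    for sample in table.samples:
        header.add_sample(sample)
    return header

_GT_TUPLES = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1), GT_MISSING: (None, None)}


def write_vcf(table: VariantTable, path, genome=None) -> None:
    """Write a VariantTable as VCF 4.2 with GT, AD and DP per sample."""
    header = _vcf_header(table, genome)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(table.n_sites):
            site = table.sites.iloc[i]
            rec = vcf.new_record(
                contig=str(site["chrom"]),
                start=int(site["pos"]) - 1,
                alleles=(str(site["ref"]), str(site["alt"])),
            )
            rec.id = None
            for j, sample in enumerate(table.samples):
                call = rec.samples[sample]
                call["GT"] = _GT_TUPLES[int(table.gt[i, j])]
                call.phased = False
                r, a = int(table.ad_ref[i, j]), int(table.ad_alt[i, j])
                if r >= 0 and a >= 0:
                    call["AD"] = (r, a)
                    call["DP"] = r + a
            vcf.write(rec)


def read_vcf(path, sample_filter: Sequence[str] | None = None) -> VariantTable:
    """Read a VCF 4.x with GT (AD optional) into a VariantTable.

    Multiallelic records are split into biallelic rows; genotypes involving
    other alternate alleles, as well as half-calls, become missing. Records
    whose ref or alt is not a single base are kept but flagged as indels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise ValueError("VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        if sample_filter is not None:
            missing = set(sample_filter) - set(samples)
            if missing:
                raise ValueError(f"samples not in VCF: {sorted(missing)}")
            samples = [s for s in samples if s in set(sample_filter)]
        rows, gts, refs_d, alts_d = [], [], [], []
        for rec in vcf:
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                row_gt = np.full(len(samples), GT_MISSING, dtype=np.int8)
                row_r = np.full(len(samples), COUNT_UNKNOWN, dtype=np.int32)
                row_a = np.full(len(samples), COUNT_UNKNOWN, dtype=np.int32)
                for j, s in enumerate(samples):
                    call = rec.samples[s]
                    alleles = call.get("GT")
                    if alleles is None or any(a is None for a in alleles) or len(alleles) != 2:
                        pass  # missing / half-call
                    else:
                        dosage = sum(a == ai for a in alleles)
                        other = any(a not in (0, ai) for a in alleles)
                        row_gt[j] = GT_MISSING if other else dosage
                    ad = call.get("AD")
                    if ad is not None and len(ad) > ai and ad[0] is not None and ad[ai] is not None:
                        row_r[j], row_a[j] = int(ad[0]), int(ad[ai])
                rows.append(
                    {
                        "chrom": rec.contig,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "is_indel": len(rec.ref) != 1 or len(alt) != 1,
                    }
                )
                gts.append(row_gt)
                refs_d.append(row_r)
                alts_d.append(row_a)
    if not rows:
        sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "is_indel"])
        empty = np.zeros((0, len(samples)), dtype=np.int8)
        return VariantTable(sites, samples, empty, empty.astype(np.int32), empty.astype(np.int32))
    sites = pd.DataFrame(rows)
    return VariantTable(sites, samples, np.array(gts), np.array(refs_d), np.array(alts_d))


# ---------------------------------------------------------------------------
# Regions / BED
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Genomic intervals, 1-based closed, with optional label and extra
    metadata columns."""

    df: pd.DataFrame

    def __post_init__(self):
        if len(self.df) == 0 and "chrom" not in self.df.columns:
            self.df = pd.DataFrame(columns=["chrom", "start", "end"])
        self.df = self.df.reset_index(drop=True)
        for col in ("chrom", "start", "end"):
            if col not in self.df.columns:
                raise ValueError(f"RegionSet missing column {col!r}")
        if len(self.df):
            if (self.df["start"] > self.df["end"]).any():
                raise ValueError("region start > end")
            if (self.df["start"] < 1).any():
                raise ValueError("regions must use 1-based positive coordinates")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(pd.DataFrame(columns=["chrom", "start", "end"]))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "RegionSet":
        rows = list(records)
        cols = ["chrom", "start", "end", "label"][: (len(rows[0]) if rows else 3)]
        return cls(pd.DataFrame(rows, columns=cols))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def merged(self) -> "RegionSet":
        """Union of intervals (labels dropped)."""
        rows = []
        for chrom in pd.unique(self.df["chrom"]):
            sub = self.for_chrom(chrom).sort_values("start")
            cur = None
            for start, end in zip(sub["start"], sub["end"]):
                if cur is None or start > cur[1] + 1:
                    if cur:
                        rows.append((chrom, cur[0], cur[1]))
                    cur = [int(start), int(end)]
                else:
                    cur[1] = max(cur[1], int(end))
            if cur:
                rows.append((chrom, cur[0], cur[1]))
        if not rows:
            return RegionSet.empty()
        return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def total_bp(self) -> int:
        m = self.merged().df
        if len(m) == 0:
            return 0
        return int((m["end"] - m["start"] + 1).sum())

    def intersect_bp(self, other: "RegionSet") -> int:
        total = 0
        a, b = self.merged().df, other.merged().df
        for chrom in pd.unique(a["chrom"]):
            sa = a[a["chrom"] == chrom]
            sb = b[b["chrom"] == chrom]
            for s1, e1 in zip(sa["start"], sa["end"]):
                lo = np.maximum(sb["start"].to_numpy(), s1)
                hi = np.minimum(sb["end"].to_numpy(), e1)
                total += int(np.maximum(hi - lo + 1, 0).sum())
        return total

    def jaccard(self, other: "RegionSet") -> float:
        inter = self.intersect_bp(other)
        union = self.total_bp() + other.total_bp() - inter
        return inter / union if union else 1.0

    def contains_point(self, chrom: str, pos: int) -> bool:
        sub = self.for_chrom(chrom)
        return bool(((sub["start"] <= pos) & (sub["end"] >= pos)).any())


def write_bed(regions: RegionSet, path) -> None:
    """Write as BED (0-based half-open); label column kept if present."""
    df = regions.df.copy()
    cols = ["chrom", "start", "end"] + (["label"] if "label" in df.columns else [])
    df = df[cols]
    df["start"] = df["start"].astype(int) - 1
    if (df["start"] < 0).any():
        raise ValueError("negative BED coordinate")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> RegionSet:
    """Read BED3(+label) into 1-based closed coordinates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return RegionSet.empty()
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    names = ["chrom", "start", "end"] + [f"c{i}" for i in range(3, df.shape[1])]
    df.columns = names
    if df.shape[1] > 3:
        df = df.rename(columns={"c3": "label"})[["chrom", "start", "end", "label"]]
    else:
        df = df[["chrom", "start", "end"]]
    if (df["start"] < 0).any():
        raise ValueError("negative BED coordinate")
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return RegionSet(df)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene: exons in coding (5'->3') order and the genomic
    CDS bounds. The summed CDS length must be divisible by 3."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_intervals(self) -> list[tuple[int, int]]:
        """Genomic CDS pieces in genomic order."""
        out = []
        for s, e in sorted(self.exons):
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]


def read_gene_models(path) -> list[GeneModel]:
    """Read a GFF-like tab table with columns
    gene_id, chrom, strand, feature (gene/exon/CDS), start, end.

    Exons are returned in coding order (reversed for minus-strand genes);
    a gene whose CDS length is not divisible by 3 is rejected with its id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene_id", "chrom", "strand", "feature", "start", "end"],
        comment="#",
    )
    models = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        chrom = sub["chrom"].iloc[0]
        strand = sub["strand"].iloc[0]
        exons = sorted(
            (int(r.start), int(r.end))
            for r in sub[sub["feature"] == "exon"].itertuples()
        )
        cds = sub[sub["feature"] == "CDS"]
        if len(cds) == 0 or not exons:
            raise ValueError(f"{gene_id}: needs exon and CDS rows")
        cds_start, cds_end = int(cds["start"].min()), int(cds["end"].max())
        if strand == "-":
            exons = exons[::-1]
        models.append(GeneModel(str(gene_id), str(chrom), str(strand), exons, cds_start, cds_end))
    return models


# ---------------------------------------------------------------------------
# Trees / newick
# ---------------------------------------------------------------------------

def write_newick(tree: skbio.TreeNode, path) -> None:
    """Serialize a tree with labelled leaves and non-negative branch lengths."""
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf labels")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    tree.write(str(path), format="newick")


def read_newick(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def write_regions_tsv(regions: RegionSet, path) -> None:
    regions.df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    """Pooled allele counts: chrom, pos, ref_<pool>, alt_<pool> columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"counts table missing column {col!r}")
    return df
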