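"""Co-segregation filtering of SNPs against phenotype groups, and a minimal
coding-effect classifier.

The co-segregation predicate is the exact rule used to pin a recessive
causal change: keep SNPs homozygous-alternate in ALL affected plants and
not homozygous-alternate in ANY unaffected plant. It is a deterministic
filter, not an association statistic. The effect classifier translates the
reference and alternate codons (strand-aware, standard code) and assigns
synonymous / nonsynonymous / stop_gained, flags variants within 2 bp of an
exon-intron boundary on the intron side as splice_site, length-changing CDS
variants of size not divisible by 3 as frameshift, and everything else as
noncoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .variant_io import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GeneModel,
    RegionSet,
    VariantTable,
)

EFFECTS = ("stop_gained", "frameshift", "splice_site", "nonsynonymous", "synonymous", "noncoding")
_SEVERITY = {e: i for i, e in enumerate(EFFECTS)}
SPLICE_WINDOW = 2  # intronic bp next to an exon boundary (canonical GT/AG)


@dataclass
class CandidateSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    pattern: dict[str, str]  # sample -> call name
    effect: str = "noncoding"
    gene_id: str | None = None


_CALL_NAMES = {GT_MISSING: "missing", GT_HOM_REF: "hom-ref", GT_HET: "het", GT_HOM_ALT: "hom-alt"}


def cosegregating_snps(
    table: VariantTable,
    affected: Sequence[str],
    unaffected: Sequence[str],
    region: RegionSet | None = None,
    max_missing: int = 0,
) -> list[CandidateSnp]:
    """SNPs whose zygosity pattern co-segregates with the phenotype.

    Kept iff hom-alt in all affected samples and not hom-alt in any
    unaffected sample; up to ``max_missing`` missing calls across both
    groups are tolerated (a missing call neither confirms nor excludes).
    """
    if not affected or not unaffected:
        raise ValueError("both groups must be non-empty")
    overlap = set(affected) & set(unaffected)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    aff_idx = [table.sample_index(s) for s in affected]
    una_idx = [table.sample_index(s) for s in unaffected]
    gt = table.gt
    aff = gt[:, aff_idx]
    una = gt[:, una_idx]
    n_missing = (aff == GT_MISSING).sum(axis=1) + (una == GT_MISSING).sum(axis=1)
    aff_ok = ((aff == GT_HOM_ALT) | (aff == GT_MISSING)).all(axis=1)
    una_ok = (una != GT_HOM_ALT).all(axis=1)
    keep = aff_ok & una_ok & (n_missing <= max_missing) & table.snp_mask()
    out = []
    for i in np.flatnonzero(keep):
        site = table.sites.iloc[i]
        if region is not None and not region.contains_point(site["chrom"], int(site["pos"])):
            continue
        pattern = {
            s: _CALL_NAMES[int(gt[i, table.sample_index(s)])]
            for s in (*affected, *unaffected)
        }
        out.append(
            CandidateSnp(str(site["chrom"]), int(site["pos"]), str(site["ref"]),
                         str(site["alt"]), pattern)
        )
    return out


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def _cds_coordinate(gene: GeneModel, pos: int) -> int | None:
    """0-based position within the spliced CDS (coding direction), or None
    if pos is not in the CDS."""
    pieces = gene.cds_intervals  # genomic order
    if gene.strand == "-":
        pieces = pieces[::-1]
    offset = 0
    for s, e in pieces:
        if s <= pos <= e:
            return offset + (pos - s if gene.strand == "+" else e - pos)
        offset += e - s + 1
    return None


def _is_splice_site(gene: GeneModel, pos: int) -> bool:
    """Within SPLICE_WINDOW bp of an exon boundary, on the intron side."""
    exons = sorted(gene.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 < pos < s2 and (pos - e1 <= SPLICE_WINDOW or s2 - pos <= SPLICE_WINDOW):
            return True
    return False


def cds_sequence(gene: GeneModel, ref_seq: Mapping[str, str]) -> str:
    """Spliced CDS in coding direction from a chrom -> sequence mapping."""
    chrom_seq = ref_seq[gene.chrom]
    parts = [chrom_seq[s - 1 : e] for s, e in gene.cds_intervals]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def classify_effect(
    snp,
    gene_models: Sequence[GeneModel],
    ref_seq: Mapping[str, str],
) -> tuple[str, str | None]:
    """Coding effect of a variant given gene models and the reference
    sequence. ``snp`` needs chrom, pos, ref, alt attributes (a CandidateSnp
    or any namespace). Returns (effect, gene_id). The reference base at the
    position must match the supplied reference sequence."""
    chrom, pos, ref, alt = snp.chrom, int(snp.pos), str(snp.ref), str(snp.alt)
    if chrom not in ref_seq:
        raise KeyError(f"chromosome {chrom!r} not in reference")
    if pos < 1 or pos > len(ref_seq[chrom]):
        raise ValueError(f"position {chrom}:{pos} outside reference")
    is_snv = len(ref) == 1 and len(alt) == 1
    if is_snv and ref_seq[chrom][pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: table says {ref!r}, "
            f"sequence has {ref_seq[chrom][pos - 1]!r}"
        )
    for gene in gene_models:
        if gene.chrom != chrom:
            continue
        lo, hi = gene.span
        if not lo <= pos <= hi:
            continue
        if _is_splice_site(gene, pos):
            return "splice_site", gene.gene_id
        cds_pos = _cds_coordinate(gene, pos)
        if cds_pos is None:
            continue  # exonic UTR or deep intron within this gene
        if not is_snv:
            if (len(alt) - len(ref)) % 3 != 0:
                return "frameshift", gene.gene_id
            return "nonsynonymous", gene.gene_id  # in-frame length change
        cds = cds_sequence(gene, ref_seq)
        codon_i = cds_pos // 3
        within = cds_pos % 3
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        base = alt if gene.strand == "+" else str(Seq(alt).complement())
        alt_codon = codon[:within] + base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_alt == "*" and aa_ref != "*":
            return "stop_gained", gene.gene_id
        if aa_alt == aa_ref:
            return "synonymous", gene.gene_id
        return "nonsynonymous", gene.gene_id
    return "noncoding", None


def annotate_candidates(
    candidates: Sequence[CandidateSnp],
    gene_models: Sequence[GeneModel],
    ref_seq: Mapping[str, str],
) -> list[CandidateSnp]:
    for c in candidates:
        c.effect, c.gene_id = classify_effect(c, gene_models, ref_seq)
    return list(candidates)


def candidate_report(candidates: Sequence[CandidateSnp]) -> pd.DataFrame:
    """Ranked candidate table: most severe effect first
    (stop_gained/frameshift > splice_site > nonsynonymous >
    synonymous/noncoding), ties broken by (chrom, pos)."""
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "effect": c.effect,
            "gene_id": c.gene_id or "",
            "pattern": ";".join(f"{s}={v}" for s, v in c.pattern.items()),
        }
        for c in candidates
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "effect", "gene_id", "pattern"]
    )
    if len(df):
        df["_sev"] = df["effect"].map(_SEVERITY)
        df = (
            df.sort_values(["_sev", "chrom", "pos"], kind="mergesort")
            .drop(columns="_sev")
            .reset_index(drop=True)
        )
        df.insert(0, "rank", np.arange(1, len(df) + 1))
    else:
        df.insert(0, "rank", pd.Series(dtype=int))
    return df
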