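"""Introgression fractions, zygosity dynamics across selfing generations,
and marker-locus (T-DNA) zygosity.

Under neutral selfing, material that was heterozygous at the outcross F1
remains heterozygous with probability (1/2)^g after g selfing generations,
the balance fixing equally to the two homozygous states. The generation
estimator inverts that decay: g-hat = round(log_1/2 of the observed het
fraction of the initially introgressed material). Note that whole-genome
donor *dosage* is invariant under selfing, so the estimator must use the
het fraction, not the donor fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sim_cross import GenomeSpec
from .variant_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, RegionSet, VariantTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genome fractions
# ---------------------------------------------------------------------------

def introgression_fraction(
    regions: RegionSet, genome: GenomeSpec, mode: str = "any"
) -> float:
    """Fraction of the genome covered by the (merged) regions.

    ``mode`` filters by the zygosity label: 'any', 'hom' (homozygous),
    'het' (heterozygous). Overlapping regions of conflicting zygosity are
    resolved by interval union within the selected class (logged)."""
    if mode not in ("any", "hom", "het"):
        raise ValueError("mode must be any/hom/het")
    df = regions.df
    if len(df) == 0:
        return 0.0
    if mode != "any" and "label" in df.columns:
        want = "homozygous" if mode == "hom" else "heterozygous"
        df = df[df["label"] == want]
    elif mode != "any":
        raise ValueError("zygosity filtering requires a label column")
    sub = RegionSet(df[["chrom", "start", "end"]].copy()) if len(df) else RegionSet.empty()
    merged = sub.merged()
    if len(df) and len(merged.df) < len(df):
        logger.debug("overlapping regions resolved by interval union")
    return merged.total_bp() / genome.total_bp


def per_chromosome_fractions(
    regions: RegionSet, genome: GenomeSpec, mode: str = "any"
) -> dict[str, float]:
    out = {}
    for chrom, length in genome.chromosomes:
        sub = regions.df[regions.df["chrom"] == chrom]
        rs = RegionSet(sub.copy()) if len(sub) else RegionSet.empty()
        covered = introgression_fraction(rs, GenomeSpec(((chrom, length),)), mode)
        out[chrom] = covered
    return out


def union_fraction(per_plant_regions: Sequence[RegionSet], genome: GenomeSpec) -> float:
    """Fraction of the genome covered by the union over all plants."""
    if not per_plant_regions:
        raise ValueError("at least one plant required")
    frames = [r.df[["chrom", "start", "end"]] for r in per_plant_regions if len(r.df)]
    if not frames:
        return 0.0
    combined = RegionSet(pd.concat(frames, ignore_index=True))
    return combined.total_bp() / genome.total_bp


# ---------------------------------------------------------------------------
# Zygosity dynamics under selfing
# ---------------------------------------------------------------------------

def expected_zygosity_after_selfing(g: int) -> tuple[float, float, float]:
    """(het, hom_donor, hom_recipient) expected fractions of initially
    heterozygous material after g selfing generations:
    het = (1/2)^g, each homozygous class (1 - (1/2)^g) / 2."""
    if g < 0:
        raise ValueError("g must be >= 0")
    het = 0.5 ** g
    hom = (1.0 - het) / 2.0
    return het, hom, hom


@dataclass
class GenerationEstimate:
    g_hat: int
    g_continuous: float
    het_fraction: float


def infer_generations(het_fraction: float) -> GenerationEstimate:
    """Invert the (1/2)^g decay: continuous estimate log_1/2(fraction) and
    its nearest integer."""
    if not 0 < het_fraction <= 1:
        raise ValueError("het fraction must be in (0, 1]")
    cont = math.log(het_fraction, 0.5)
    return GenerationEstimate(round(cont), cont, het_fraction)


def observed_het_fraction(
    table: VariantTable, samples: Sequence[str], marker_rows: np.ndarray
) -> float:
    """Mean heterozygous-call fraction over the given samples at the given
    site rows (the initially introgressed, i.e. F1-heterozygous, markers).
    Missing calls are excluded from each sample's denominator."""
    fracs = []
    for s in samples:
        gt = table.gt_for(s)[marker_rows]
        called = gt != GT_MISSING
        if called.sum() == 0:
            continue
        fracs.append(float((gt[called] == GT_HET).mean()))
    if not fracs:
        raise ValueError("no genotyped markers for any sample")
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# Region trajectories across generations
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def track_fixation(
    region_sets_by_generation: Mapping[str, RegionSet],
    min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Match regions across an ordered mapping generation -> RegionSet by
    reciprocal overlap and label each chain's zygosity trajectory
    (het->het, het->hom, het->lost, hom->hom, ...).

    Returns a table with one row per chain: the seed region, per-generation
    matched zygosity ('lost' where unmatched), and the trajectory string.
    Later-generation regions with no earlier match are flagged as new
    chains starting at their generation."""
    gens = list(region_sets_by_generation)
    if not gens:
        raise ValueError("empty generation list")
    chains: list[dict] = []
    for gi, gen in enumerate(gens):
        rs = region_sets_by_generation[gen]
        for row in rs.df.itertuples(index=False):
            label = getattr(row, "label", "unknown")
            matched = False
            for chain in chains:
                if chain["chrom"] != row.chrom or chain["states"].get(gen) is not None:
                    continue
                ov = _reciprocal_overlap(
                    (chain["start"], chain["end"]), (row.start, row.end)
                )
                if ov >= min_reciprocal_overlap:
                    chain["states"][gen] = label
                    chain["start"], chain["end"] = int(row.start), int(row.end)
                    matched = True
                    break
            if not matched:
                states = {g: None for g in gens}
                states[gen] = label
                chains.append(
                    {
                        "chrom": row.chrom,
                        "start": int(row.start),
                        "end": int(row.end),
                        "first_gen": gen,
                        "states": states,
                    }
                )
                if gi > 0:
                    logger.info(
                        "region %s:%d-%d appears first in generation %s",
                        row.chrom, row.start, row.end, gen,
                    )
    rows = []
    short = {"heterozygous": "het", "homozygous": "hom", "mixed": "mixed"}
    for chain in chains:
        seen = [
            short.get(chain["states"][g], chain["states"][g]) or "lost"
            for g in gens
            if gens.index(g) >= gens.index(chain["first_gen"])
        ]
        trajectory = "->".join([seen[0], seen[-1]]) if len(seen) > 1 else seen[0]
        rows.append(
            {
                "chrom": chain["chrom"],
                "start": chain["start"],
                "end": chain["end"],
                "first_generation": chain["first_gen"],
                **{f"state_{g}": chain["states"][g] or "lost" for g in gens},
                "trajectory": trajectory,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Locus zygosity (T-DNA analogue)
# ---------------------------------------------------------------------------

LOCUS_STATES = {
    GT_HOM_ALT: "homozygous",
    GT_HET: "heterozygous",
    GT_HOM_REF: "azygous",
    GT_MISSING: "missing",
}


def classify_locus_zygosity(
    table: VariantTable, sample: str, locus: tuple[str, int]
) -> str:
    """Zygosity of a presence/absence marker (e.g. the T-DNA insertion):
    hom-alt -> homozygous, het -> heterozygous, hom-ref -> azygous,
    uncallable -> missing."""
    chrom, pos = locus
    rows = table.site_rows(chrom, pos, pos)
    if len(rows) == 0:
        raise KeyError(f"locus {chrom}:{pos} not in table")
    gt = int(table.gt[rows[0], table.sample_index(sample)])
    return LOCUS_STATES[gt]


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def lineage_summary(
    per_plant_regions: Mapping[str, RegionSet],
    genome: GenomeSpec,
) -> pd.DataFrame:
    """Per-plant introgressed fractions (any / het / hom) and the union
    fraction across all plants (repeated on each row for convenience)."""
    union = union_fraction(list(per_plant_regions.values()), genome)
    rows = []
    for plant, rs in per_plant_regions.items():
        rows.append(
            {
                "plant": plant,
                "fraction_any": introgression_fraction(rs, genome, "any"),
                "fraction_het": introgression_fraction(rs, genome, "het")
                if "label" in rs.df.columns or len(rs.df) == 0
                else float("nan"),
                "fraction_hom": introgression_fraction(rs, genome, "hom")
                if "label" in rs.df.columns or len(rs.df) == 0
                else float("nan"),
                "union_fraction": union,
            }
        )
    return pd.DataFrame(rows)
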