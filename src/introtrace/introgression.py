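"""Detection of donor-introgression segments from SNP density.

The detector follows the rule-based procedure used for graphical genotyping
of an outcrossed selfing line: a sliding-window SNP-density plot (density
expressed as SNPs per 2 Mb regardless of window width), windows called
"high" against control samples, maximal runs merged into raw regions,
borders refined to 10 kb beyond the outermost sample-specific SNP, zygosity
classified from the het/hom composition of the region's calls, and an
optional donor-similarity score against a known donor sample. A genome-state
classifier separates clean genomes, segmental introgression, and the
genome-wide-heterozygous signature of a fresh outcross (F1).

No HMM or IBD-likelihood machinery is used: the procedure is deliberately
the explicit windowed rule set, with every threshold configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    RegionSet,
    VariantTable,
)
from .sim_cross import GenomeSpec

logger = logging.getLogger(__name__)

DENSITY_UNIT_BP = 2_000_000  # densities are reported per 2 Mb


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    """Thresholds of the windowed introgression detector.

    window / step: sliding-window width and anchor spacing in bp. The
    full-scale defaults (2 Mb / 5 kb) suit real rice chromosomes; use
    ``desk_scale()`` for the 2.5-Mb simulation chromosomes, where 100 kb is
    the proportional window.
    fold / min_abs: a window is high iff its density (per 2 Mb) is at least
    ``min_abs`` and at least ``fold`` times the strongest control window
    (controls floored at 1 per 2 Mb).
    min_region_snps: minimum sample-specific SNPs to keep a region.
    pad: border padding beyond the outermost sample-specific SNP (bp).
    het_hi / het_lo: heterozygous-call fraction bounds for zygosity calls.
    """

    window: int = 2_000_000
    step: int = 5_000
    fold: float = 10.0
    min_abs: float = 50.0
    min_region_snps: int = 10
    pad: int = 10_000
    het_hi: float = 0.8
    het_lo: float = 0.2

    def __post_init__(self):
        if self.window < self.step:
            raise ValueError("window width must be >= step")

    @classmethod
    def desk_scale(cls, **overrides) -> "DetectionParams":
        defaults = dict(window=100_000, step=5_000)
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Density track
# ---------------------------------------------------------------------------

@dataclass
class DensityTrack:
    """Per-chromosome sliding windows with SNP counts and densities in
    SNPs per 2 Mb."""

    sample: str
    window: int
    step: int
    by_chrom: dict[str, pd.DataFrame]  # columns start, end, snp_count, density

    def same_grid(self, other: "DensityTrack") -> bool:
        if set(self.by_chrom) != set(other.by_chrom):
            return False
        return all(
            len(self.by_chrom[c]) == len(other.by_chrom[c])
            and (self.by_chrom[c]["start"].to_numpy() == other.by_chrom[c]["start"].to_numpy()).all()
            for c in self.by_chrom
        )

    def to_frame(self) -> pd.DataFrame:
        frames = [df.assign(chrom=c) for c, df in self.by_chrom.items()]
        return pd.concat(frames, ignore_index=True)[
            ["chrom", "start", "end", "snp_count", "density"]
        ]


def snp_density_track(
    table: VariantTable,
    sample: str,
    genome: GenomeSpec,
    width: int = 2_000_000,
    step: int = 5_000,
    include: str = "all",
) -> DensityTrack:
    """SNP-density sliding windows for one sample.

    One window is anchored every ``step`` bp from position 1; a non-reference
    call is counted in every window containing it. Trailing windows are
    truncated at the chromosome end and their density rescaled to per-2-Mb
    units (density = snp_count * 2e6 / actual window length). ``include``
    selects all non-reference calls or heterozygous calls only.
    """
    if width < step:
        raise ValueError("width must be >= step")
    if include not in ("all", "het_only"):
        raise ValueError("include must be 'all' or 'het_only'")
    gt = table.gt_for(sample)
    snp = table.snp_mask()
    if include == "all":
        keep = (gt == GT_HET) | (gt == GT_HOM_ALT)
    else:
        keep = gt == GT_HET
    keep &= snp
    by_chrom = {}
    for chrom, length in genome.chromosomes:
        rows = table.site_rows(chrom)
        pos = np.sort(table.sites["pos"].to_numpy()[rows[keep[rows]]])
        starts = np.arange(1, length + 1, step, dtype=np.int64)
        ends = np.minimum(starts + width - 1, length)
        counts = np.searchsorted(pos, ends, side="right") - np.searchsorted(
            pos, starts, side="left"
        )
        span = (ends - starts + 1).astype(float)
        density = counts * (DENSITY_UNIT_BP / span)
        by_chrom[chrom] = pd.DataFrame(
            {"start": starts, "end": ends, "snp_count": counts, "density": density}
        )
    return DensityTrack(sample, width, step, by_chrom)


# ---------------------------------------------------------------------------
# High-density region calling
# ---------------------------------------------------------------------------

def call_high_density_regions(
    sample_track: DensityTrack,
    control_tracks: Sequence[DensityTrack],
    fold: float = 10.0,
    min_abs: float = 50.0,
) -> RegionSet:
    """Raw candidate regions: maximal runs of windows whose density is at
    least ``min_abs`` per 2 Mb AND at least ``fold`` times the maximum
    control density (floored at 1 per 2 Mb). Runs separated by less than one
    window width are merged."""
    if not control_tracks:
        raise ValueError("at least one control track is required")
    for ct in control_tracks:
        if not sample_track.same_grid(ct):
            raise ValueError("control tracks must share the sample's window grid")
    rows = []
    for chrom, df in sample_track.by_chrom.items():
        dens = df["density"].to_numpy()
        ctrl = np.maximum.reduce(
            [ct.by_chrom[chrom]["density"].to_numpy() for ct in control_tracks]
        )
        high = (dens >= min_abs) & (dens >= fold * np.maximum(ctrl, 1.0))
        if not high.any():
            continue
        idx = np.flatnonzero(high)
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i == prev + 1:
                prev = i
                continue
            runs.append((run_start, prev))
            run_start = prev = i
        runs.append((run_start, prev))
        # merge runs whose genomic gap is smaller than one window width
        merged = [list(runs[0])]
        for a, b in runs[1:]:
            gap = starts[a] - ends[merged[-1][1]] - 1
            if gap < sample_track.window:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            rows.append((chrom, int(starts[a]), int(ends[b])))
    if not rows:
        return RegionSet.empty()
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


# ---------------------------------------------------------------------------
# Sample-specific sites and border refinement
# ---------------------------------------------------------------------------

def sample_specific_mask(
    table: VariantTable, sample: str, controls: Sequence[str]
) -> np.ndarray:
    """True at SNP sites where the sample is non-reference and every control
    is reference or missing. Missing control calls are non-informative, not
    matches."""
    gt = table.gt_for(sample)
    nonref = (gt == GT_HET) | (gt == GT_HOM_ALT)
    for c in controls:
        cgt = table.gt_for(c)
        nonref &= (cgt == GT_HOM_REF) | (cgt == GT_MISSING)
    return nonref & table.snp_mask()


def refine_borders(
    raw_region: tuple[str, int, int],
    specific_positions: np.ndarray,
    chrom_length: int,
    pad: int = 10_000,
    min_region_snps: int = 10,
) -> tuple[int, int, int] | None:
    """Refine a raw region's borders to ``pad`` bp beyond the outermost
    sample-specific SNP inside it, clipped to chromosome bounds.

    Returns (start, end, n_specific_snps), or None (with a log notice) when
    fewer than ``min_region_snps`` sample-specific SNPs fall in the raw
    region."""
    chrom, start, end = raw_region
    pos = np.asarray(specific_positions)
    inside = pos[(pos >= start) & (pos <= end)]
    if len(inside) < min_region_snps:
        logger.info(
            "region %s:%d-%d dropped: %d sample-specific SNPs < %d",
            chrom, start, end, len(inside), min_region_snps,
        )
        return None
    lo = max(1, int(inside.min()) - pad)
    hi = min(chrom_length, int(inside.max()) + pad)
    return lo, hi, int(len(inside))


# ---------------------------------------------------------------------------
# Zygosity
# ---------------------------------------------------------------------------

HOMOZYGOUS, HETEROZYGOUS, MIXED = "homozygous", "heterozygous", "mixed"


def classify_zygosity(
    region: tuple[str, int, int],
    table: VariantTable,
    sample: str,
    het_hi: float = 0.8,
    het_lo: float = 0.2,
) -> str:
    """Zygosity of a region from the het fraction among its non-reference
    calls: heterozygous above ``het_hi``, homozygous below ``het_lo``,
    otherwise mixed (candidate internal recombination)."""
    chrom, start, end = region
    rows = table.site_rows(chrom, start, end)
    gt = table.gt[rows, table.sample_index(sample)]
    het = int((gt == GT_HET).sum())
    hom = int((gt == GT_HOM_ALT).sum())
    if het + hom == 0:
        raise ValueError(f"no genotyped non-reference sites in {chrom}:{start}-{end}")
    frac = het / (het + hom)
    if frac >= het_hi:
        return HETEROZYGOUS
    if frac <= het_lo:
        return HOMOZYGOUS
    return MIXED


def donor_similarity(
    region: tuple[str, int, int],
    table: VariantTable,
    sample: str,
    donor_sample: str,
) -> float:
    """Fraction of the sample's non-reference sites in the region at which
    the donor carries the same alternate allele."""
    chrom, start, end = region
    rows = table.site_rows(chrom, start, end)
    gt = table.gt[rows, table.sample_index(sample)]
    dgt = table.gt[rows, table.sample_index(donor_sample)]
    nonref = (gt == GT_HET) | (gt == GT_HOM_ALT)
    if not nonref.any():
        raise ValueError("zero non-reference sites in region")
    donor_has = (dgt == GT_HET) | (dgt == GT_HOM_ALT)
    return float((nonref & donor_has).sum() / nonref.sum())


# ---------------------------------------------------------------------------
# Full detector
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionRegion:
    chrom: str
    start: int
    end: int
    zygosity: str
    snp_count: int
    donor_similarity: float = float("nan")

    def as_tuple(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _split_mixed(
    region: tuple[str, int, int],
    table: VariantTable,
    sample: str,
    params: DetectionParams,
) -> list[tuple[str, int, int]]:
    """Recursively split a mixed region at the strongest het/hom run
    boundary (the change point with the largest flanking same-state runs),
    provided both halves keep at least min_region_snps non-reference sites."""
    chrom, start, end = region
    rows = table.site_rows(chrom, start, end)
    gt = table.gt[rows, table.sample_index(sample)]
    keep = (gt == GT_HET) | (gt == GT_HOM_ALT)
    pos = table.sites["pos"].to_numpy()[rows][keep]
    state = (gt[keep] == GT_HET).astype(int)
    n = len(state)
    if n < 2 * params.min_region_snps:
        return [region]
    change = np.flatnonzero(state[1:] != state[:-1]) + 1
    if len(change) == 0:
        return [region]
    run_id = np.concatenate([[0], np.cumsum(state[1:] != state[:-1])])
    run_len = np.bincount(run_id)
    best, best_score = None, -1
    for k in change:
        left, right = run_id[k - 1], run_id[k]
        score = min(run_len[left], run_len[right])
        if score > best_score and k >= params.min_region_snps and n - k >= params.min_region_snps:
            best, best_score = k, score
    if best is None:
        return [region]
    left = (chrom, start, int((pos[best - 1] + pos[best]) // 2))
    right = (chrom, left[2] + 1, end)
    out = []
    for half in (left, right):
        z = classify_zygosity(half, table, sample, params.het_hi, params.het_lo)
        if z == MIXED:
            out.extend(_split_mixed(half, table, sample, params))
        else:
            out.append(half)
    return out


def detect_introgression(
    table: VariantTable,
    sample: str,
    controls: Sequence[str],
    genome: GenomeSpec,
    donor_sample: str | None = None,
    params: DetectionParams | None = None,
) -> list[IntrogressionRegion]:
    """End-to-end detector: density track vs controls, raw region calling,
    border refinement on sample-specific SNPs, zygosity classification with
    mixed-region splitting, and optional donor similarity."""
    params = params or DetectionParams()
    if not controls:
        raise ValueError("controls are required")
    strack = snp_density_track(table, sample, genome, params.window, params.step)
    ctracks = [
        snp_density_track(table, c, genome, params.window, params.step) for c in controls
    ]
    raw = call_high_density_regions(strack, ctracks, params.fold, params.min_abs)
    specific = sample_specific_mask(table, sample, controls)
    lengths = genome.lengths
    out: list[IntrogressionRegion] = []
    for row in raw.df.itertuples(index=False):
        chrom = row.chrom
        rows = table.site_rows(chrom)
        spos = table.sites["pos"].to_numpy()[rows][specific[rows]]
        refined = refine_borders(
            (chrom, row.start, row.end), spos, lengths[chrom], params.pad,
            params.min_region_snps,
        )
        if refined is None:
            continue
        lo, hi, _ = refined
        zyg = classify_zygosity((chrom, lo, hi), table, sample, params.het_hi, params.het_lo)
        pieces = (
            _split_mixed((chrom, lo, hi), table, sample, params)
            if zyg == MIXED
            else [(chrom, lo, hi)]
        )
        for chrom_p, a, b in pieces:
            # re-refine each piece so borders hug its own SNPs
            refined_p = refine_borders(
                (chrom_p, a, b), spos, lengths[chrom_p], params.pad, params.min_region_snps
            )
            if refined_p is None:
                continue
            a2, b2, n_spec = refined_p
            zyg_p = classify_zygosity(
                (chrom_p, a2, b2), table, sample, params.het_hi, params.het_lo
            )
            sim = float("nan")
            if donor_sample is not None:
                sim = donor_similarity((chrom_p, a2, b2), table, sample, donor_sample)
            out.append(IntrogressionRegion(chrom_p, a2, b2, zyg_p, n_spec, sim))
    return out


def regions_to_regionset(regions: Sequence[IntrogressionRegion]) -> RegionSet:
    if not regions:
        return RegionSet.empty()
    return RegionSet(
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "label": r.zygosity,
                    "snp_count": r.snp_count,
                    "donor_similarity": r.donor_similarity,
                }
                for r in regions
            ]
        )
    )


# ---------------------------------------------------------------------------
# Heterozygosity profile and genome state
# ---------------------------------------------------------------------------

@dataclass
class HetProfile:
    """Fixed-bin (default 100 kb) heterozygous-SNP counts per chromosome."""

    sample: str
    bin_size: int
    by_chrom: dict[str, np.ndarray]

    @property
    def counts(self) -> np.ndarray:
        return np.concatenate(list(self.by_chrom.values()))


def het_profile(
    table: VariantTable, sample: str, genome: GenomeSpec, bin_size: int = 100_000
) -> HetProfile:
    """Heterozygous-call counts in fixed bins tiling each chromosome;
    position p belongs to bin ceil(p / bin_size)."""
    gt = table.gt_for(sample)
    het = (gt == GT_HET) & table.snp_mask()
    by_chrom = {}
    for chrom, length in genome.chromosomes:
        n_bins = int(np.ceil(length / bin_size))
        rows = table.site_rows(chrom)
        pos = table.sites["pos"].to_numpy()[rows[het[rows]]]
        bins = (pos - 1) // bin_size
        by_chrom[chrom] = np.bincount(bins, minlength=n_bins).astype(np.int64)
    return HetProfile(sample, bin_size, by_chrom)


CLEAN = "clean"
SEGMENTAL = "segmental_introgression"
GENOME_WIDE_HET = "genome_wide_heterozygous"


def classify_genome_state(
    profile: HetProfile,
    regions: Sequence[IntrogressionRegion] | RegionSet,
    het_floor: int = 10,
    genome_wide_frac: float = 0.90,
    clean_frac: float = 0.01,
) -> str:
    """Genome state from the het profile and the called regions:
    genome-wide heterozygosity (a fresh outcross) when >= 90% of bins exceed
    the het-count floor; clean when no regions were called and <= 1% of bins
    exceed it; segmental introgression otherwise."""
    counts = profile.counts
    frac_high = float((counts > het_floor).mean()) if len(counts) else 0.0
    n_regions = len(regions.df) if isinstance(regions, RegionSet) else len(regions)
    if frac_high >= genome_wide_frac:
        return GENOME_WIDE_HET
    if n_regions == 0 and frac_high <= clean_frac:
        return CLEAN
    return SEGMENTAL
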