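"""Forward simulator of a rice-like outcross / selfing / tissue-culture pedigree.

The simulator produces exactly the data structure the downstream inference
assumes: a japonica-like recipient genome, an indica-like donor differing at
high marker density, a second japonica-like mapping parent, meiotic
recombination without interference, tissue-culture point mutations, a T-DNA
insertion modelled as a presence/absence pseudo-marker, fully penetrant
recessive causal loci, and short-read allele counts for single plants or
20-plant DNA pools.

Every simulated plant exposes its true ancestry mosaic so that detector
output can be scored against truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Ancestry and marker-class codes
# ---------------------------------------------------------------------------

RECIPIENT, DONOR, PARENT2 = 0, 1, 2
ANCESTRY_NAMES = {RECIPIENT: "recipient", DONOR: "donor", PARENT2: "parent2"}

DONOR_DIAGNOSTIC = "donor-diagnostic"
PARENT2_DIAGNOSTIC = "parent2-diagnostic"
CULTURE_MUTATION = "culture-mutation"
TDNA_PROXY = "tdna-proxy"
MARKER_CLASSES = (DONOR_DIAGNOSTIC, PARENT2_DIAGNOSTIC, CULTURE_MUTATION, TDNA_PROXY)

_BASES = np.array(list("ACGT"))

# Genotype call codes shared with variant_io (value == alt-allele dosage).
GT_MISSING, GT_HOM_REF, GT_HET, GT_HOM_ALT = -1, 0, 1, 2


# ---------------------------------------------------------------------------
# Genome and marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths (bp, 1-based inclusive)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def default(cls, n_chromosomes: int = 12, length: int = 2_500_000) -> "GenomeSpec":
        """Desk-scale genome: 12 chromosomes of 2.5 Mb each."""
        return cls(tuple((f"chr{i+1:02d}", length) for i in range(n_chromosomes)))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)


class MarkerPanel:
    """Biallelic marker catalogue: chrom, 1-based pos, ref/alt base, class.

    Sites are kept sorted by (genome chromosome order, position) and unique
    per (chrom, pos). The panel grows during a pedigree run as culture
    mutations and the T-DNA pseudo-marker are added.
    """

    def __init__(self, genome: GenomeSpec, df: pd.DataFrame):
        self.genome = genome
        df = df.reset_index(drop=True)
        for col in ("chrom", "pos", "ref", "alt", "mclass"):
            if col not in df.columns:
                raise ValueError(f"marker table missing column {col!r}")
        self.df = self._sort(df)
        self._index = None  # lazy (chrom, pos) -> row mapping
        if (self.df["ref"] == self.df["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        dup = self.df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate marker positions in panel")

    def _sort(self, df: pd.DataFrame) -> pd.DataFrame:
        order = {name: i for i, name in enumerate(self.genome.names)}
        key = df["chrom"].map(order)
        if key.isna().any():
            raise ValueError("marker chromosome not in genome")
        return (
            df.assign(_k=key)
            .sort_values(["_k", "pos"], kind="mergesort")
            .drop(columns="_k")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def site_index(self) -> dict[tuple[str, int], int]:
        if self._index is None or len(self._index) != len(self.df):
            self._index = {
                (c, int(p)): i
                for i, (c, p) in enumerate(zip(self.df["chrom"], self.df["pos"]))
            }
        return self._index

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def rows_for(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def with_markers(self, new: pd.DataFrame) -> "MarkerPanel":
        return MarkerPanel(self.genome, pd.concat([self.df, new], ignore_index=True))

    def locus_row(self, chrom: str, pos: int) -> int:
        try:
            return self.site_index[(chrom, int(pos))]
        except KeyError:
            raise KeyError(f"locus {chrom}:{pos} not in marker panel") from None


# ---------------------------------------------------------------------------
# Haplotypes and plants
# ---------------------------------------------------------------------------

class Mosaic:
    """Ancestry mosaic of one chromosome set: per chromosome an ordered array
    of (start, end, ancestry) rows, 1-based inclusive, tiling exactly."""

    def __init__(self, genome: GenomeSpec, segments: Mapping[str, np.ndarray]):
        self.genome = genome
        self.segments = {c: np.asarray(s, dtype=np.int64) for c, s in segments.items()}
        lengths = genome.lengths
        for chrom, seg in self.segments.items():
            if seg.ndim != 2 or seg.shape[1] != 3:
                raise ValueError("segments must be (n, 3) arrays")
            if seg[0, 0] != 1 or seg[-1, 1] != lengths[chrom]:
                raise ValueError(f"segments do not tile {chrom}")
            if len(seg) > 1 and not (seg[1:, 0] == seg[:-1, 1] + 1).all():
                raise ValueError(f"gap or overlap in {chrom} mosaic")

    @classmethod
    def uniform(cls, genome: GenomeSpec, ancestry: int) -> "Mosaic":
        return cls(
            genome,
            {c: np.array([[1, L, ancestry]]) for c, L in genome.chromosomes},
        )

    def ancestry_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        seg = self.segments[chrom]
        idx = np.searchsorted(seg[:, 1], pos, side="left")
        return seg[idx, 2]

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Rows of the mosaic clipped to [start, end]."""
        seg = self.segments[chrom]
        keep = (seg[:, 1] >= start) & (seg[:, 0] <= end)
        out = seg[keep].copy()
        out[0, 0] = max(out[0, 0], start)
        out[-1, 1] = min(out[-1, 1], end)
        return out


def _merge_adjacent(rows: np.ndarray) -> np.ndarray:
    """Coalesce touching rows with identical ancestry."""
    if len(rows) <= 1:
        return rows
    out = [rows[0].copy()]
    for row in rows[1:]:
        if row[2] == out[-1][2] and row[0] == out[-1][1] + 1:
            out[-1][1] = row[1]
        else:
            out.append(row.copy())
    return np.array(out)


@dataclass(frozen=True)
class Haplotype:
    """One chromosome set: ancestry mosaic plus private variant sites
    (tissue-culture mutations and the T-DNA pseudo-marker)."""

    mosaic: Mosaic
    private: frozenset = frozenset()  # of (chrom, pos)


@dataclass(frozen=True)
class SimPlant:
    """A diploid plant: two haplotypes over a shared genome."""

    name: str
    haplotypes: tuple[Haplotype, Haplotype]
    genome: GenomeSpec

    def dosage(self, panel: MarkerPanel) -> np.ndarray:
        """Alt-allele dosage (0/1/2) at every panel site."""
        return dosage_matrix(panel, [self])[:, 0]

    def dosage_at(self, panel: MarkerPanel, chrom: str, pos: int) -> int:
        row = panel.locus_row(chrom, pos)
        mclass = panel.df["mclass"].iat[row]
        d = 0
        for hap in self.haplotypes:
            d += _hap_allele(hap, mclass, chrom, pos)
        return d

    def tdna_dosage(self, panel: MarkerPanel) -> int:
        rows = panel.df.index[panel.df["mclass"] == TDNA_PROXY]
        if len(rows) == 0:
            return 0
        chrom = panel.df["chrom"].iat[rows[0]]
        pos = int(panel.df["pos"].iat[rows[0]])
        return self.dosage_at(panel, chrom, pos)


def _hap_allele(hap: Haplotype, mclass: str, chrom: str, pos: int) -> int:
    if (chrom, pos) in hap.private:
        return 1
    if mclass == DONOR_DIAGNOSTIC:
        return int(hap.mosaic.ancestry_at(chrom, np.array([pos]))[0] == DONOR)
    if mclass == PARENT2_DIAGNOSTIC:
        return int(hap.mosaic.ancestry_at(chrom, np.array([pos]))[0] == PARENT2)
    return 0


def dosage_matrix(panel: MarkerPanel, plants: Sequence[SimPlant]) -> np.ndarray:
    """Alt-allele dosage (sites x plants), vectorised per chromosome."""
    n = len(panel)
    out = np.zeros((n, len(plants)), dtype=np.int8)
    mclass = panel.df["mclass"].to_numpy()
    is_donor = mclass == DONOR_DIAGNOSTIC
    is_p2 = mclass == PARENT2_DIAGNOSTIC
    site_index = panel.site_index
    for chrom in panel.genome.names:
        rows = panel.rows_for(chrom)
        if len(rows) == 0:
            continue
        pos = panel.df["pos"].to_numpy()[rows]
        for j, plant in enumerate(plants):
            for hap in plant.haplotypes:
                anc = hap.mosaic.ancestry_at(chrom, pos)
                allele = (is_donor[rows] & (anc == DONOR)) | (is_p2[rows] & (anc == PARENT2))
                out[rows, j] += allele.astype(np.int8)
    for j, plant in enumerate(plants):
        for hap in plant.haplotypes:
            for site in hap.private:
                row = site_index.get(site)
                if row is not None:
                    out[row, j] += 1
    return out


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Tunable rates of the forward simulation.

    crossover_lambda
        Mean crossovers per chromosome per meiosis (Poisson, no interference).
        1.25 approximates the rice genetic map length divided by 12.
    culture_mutation_rate
        Point mutations per site per diploid genome per culture passage;
        the default sits inside the measured tissue-culture range
        (0.89-2.10 per Mb per diploid genome).
    depth_mean / pool_depth_mean
        Mean short-read depth per site for single plants / DNA pools.
    base_error
        Per-read probability that the observed allele is flipped.
    """

    seed: int = 0
    crossover_lambda: float = 1.25
    culture_mutation_rate: float = 1.5e-6
    depth_mean: float = 15.0
    pool_depth_mean: float = 15.0
    base_error: float = 0.005
    min_depth: int = 4
    hom_frac: float = 0.8

    def __post_init__(self):
        if self.crossover_lambda < 0:
            raise ValueError("crossover_lambda must be >= 0")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")
        if self.culture_mutation_rate < 0:
            raise ValueError("culture_mutation_rate must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def _draw_marker_positions(
    genome: GenomeSpec, density: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Poisson(density * length) markers per chromosome, uniform positions."""
    if density > 1.0:
        raise ValueError("marker density implies inter-marker spacing < 1 bp")
    out = {}
    for chrom, length in genome.chromosomes:
        n = min(rng.poisson(density * length), length)
        # uniform positions deduplicated; collision loss is negligible at
        # the densities the error check above allows
        out[chrom] = np.unique(rng.integers(1, length + 1, size=n))
    return out


def make_founders(
    genome: GenomeSpec,
    donor_density: float,
    parent2_density: float,
    seed: int | np.random.Generator,
) -> tuple[MarkerPanel, SimPlant, SimPlant, SimPlant]:
    """Build the marker panel and three fully homozygous founders.

    The recipient is homozygous reference at every marker; the donor is
    homozygous alternate at donor-diagnostic markers; the second (mapping)
    parent is homozygous alternate at parent2-diagnostic markers. Marker
    densities mirror the contrast between indica-vs-reference (millions of
    SNPs genome-wide) and japonica-vs-japonica (tens of thousands).
    """
    if donor_density <= 0:
        raise ValueError("donor_density must be > 0")
    if parent2_density < 0:
        raise ValueError("parent2_density must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    frames = []
    donor_pos = _draw_marker_positions(genome, donor_density, rng)
    p2_pos = (
        _draw_marker_positions(genome, parent2_density, rng)
        if parent2_density > 0
        else {c: np.array([], dtype=np.int64) for c in genome.names}
    )
    for chrom in genome.names:
        dp = donor_pos[chrom]
        # drop parent2 markers colliding with donor markers
        pp = np.setdiff1d(p2_pos[chrom], dp)
        pos = np.concatenate([dp, pp])
        cls = np.concatenate(
            [np.repeat(DONOR_DIAGNOSTIC, len(dp)), np.repeat(PARENT2_DIAGNOSTIC, len(pp))]
        )
        ref_i = rng.integers(0, 4, size=len(pos))
        alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": _BASES[ref_i],
                    "alt": _BASES[alt_i],
                    "mclass": cls,
                }
            )
        )
    panel = MarkerPanel(genome, pd.concat(frames, ignore_index=True))

    def founder(name: str, ancestry: int) -> SimPlant:
        hap = Haplotype(Mosaic.uniform(genome, ancestry))
        return SimPlant(name, (hap, hap), genome)

    return (
        panel,
        founder("recipient", RECIPIENT),
        founder("donor", DONOR),
        founder("parent2", PARENT2),
    )


# ---------------------------------------------------------------------------
# Meiosis and crossing
# ---------------------------------------------------------------------------

def draw_crossovers(length: int, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover breakpoints on one chromosome: Poisson(lam) count, uniform
    positions, no interference. A breakpoint at b switches parental copy
    after position b."""
    k = rng.poisson(lam)
    if k == 0:
        return np.array([], dtype=np.int64)
    cuts = np.unique(rng.integers(1, length, size=k))
    return cuts


def meiosis(plant: SimPlant, lam: float, rng: np.random.Generator) -> Haplotype:
    """One gamete: per chromosome, alternate parental copies at Poisson(lam)
    uniform breakpoints starting from a fair-coin choice of copy."""
    segments: dict[str, list[np.ndarray]] = {}
    private: set[tuple[str, int]] = set()
    for chrom, length in plant.genome.chromosomes:
        cuts = draw_crossovers(length, lam, rng)
        bounds = np.concatenate([[0], cuts, [length]])
        src = int(rng.integers(2))
        rows = []
        for i in range(len(bounds) - 1):
            a, b = int(bounds[i]) + 1, int(bounds[i + 1])
            hap = plant.haplotypes[(src + i) % 2]
            rows.append(hap.mosaic.slice(chrom, a, b))
            for (c, p) in hap.private:
                if c == chrom and a <= p <= b:
                    private.add((c, p))
        segments[chrom] = _merge_adjacent(np.vstack(rows))
    mosaic = Mosaic(plant.genome, segments)
    return Haplotype(mosaic, frozenset(private))


def cross(
    p1: SimPlant, p2: SimPlant, lam: float, rng: np.random.Generator, name: str = "offspring"
) -> SimPlant:
    """Offspring of two plants: one independent gamete from each parent."""
    return SimPlant(name, (meiosis(p1, lam, rng), meiosis(p2, lam, rng)), p1.genome)


def self_plant(
    plant: SimPlant, lam: float, rng: np.random.Generator, name: str = "self"
) -> SimPlant:
    """Self-pollination: two independent gametes from the same plant."""
    return cross(plant, plant, lam, rng, name)


# ---------------------------------------------------------------------------
# Tissue culture: point mutations and T-DNA insertion
# ---------------------------------------------------------------------------

def apply_culture_mutations(
    plant: SimPlant, mu: float, rng: np.random.Generator, panel: MarkerPanel
) -> tuple[SimPlant, MarkerPanel]:
    """Add Poisson(mu * genome bp) de-novo point mutations, each heterozygous
    on one random haplotype, at positions not colliding with existing markers.
    Returns the mutated plant and the extended marker panel."""
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    genome = plant.genome
    n = rng.poisson(mu * genome.total_bp)
    if n == 0:
        return plant, panel
    lengths = np.array([L for _, L in genome.chromosomes], dtype=float)
    names = genome.names
    taken = set(panel.site_index)
    new_rows = []
    new_private: list[set] = [set(), set()]
    while len(new_rows) < n:
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        pos = int(rng.integers(1, genome.chromosomes[ci][1] + 1))
        site = (names[ci], pos)
        if site in taken:
            continue
        taken.add(site)
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        new_rows.append(
            {
                "chrom": names[ci],
                "pos": pos,
                "ref": _BASES[ref_i],
                "alt": _BASES[alt_i],
                "mclass": CULTURE_MUTATION,
            }
        )
        new_private[int(rng.integers(2))].add(site)
    panel = panel.with_markers(pd.DataFrame(new_rows))
    haps = tuple(
        Haplotype(h.mosaic, h.private | frozenset(new_private[i]))
        for i, h in enumerate(plant.haplotypes)
    )
    return replace(plant, haplotypes=haps), panel


def insert_tdna(
    plant: SimPlant, chrom: str, pos: int, panel: MarkerPanel
) -> tuple[SimPlant, MarkerPanel]:
    """Insert the T-DNA as a biallelic presence pseudo-marker on one
    haplotype (dosage 1); it segregates Mendelianly thereafter."""
    lengths = plant.genome.lengths
    if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
        raise ValueError(f"T-DNA position {chrom}:{pos} out of range")
    if (chrom, pos) in panel.site_index:
        raise ValueError("T-DNA position collides with an existing marker")
    panel = panel.with_markers(
        pd.DataFrame(
            [{"chrom": chrom, "pos": pos, "ref": "A", "alt": "T", "mclass": TDNA_PROXY}]
        )
    )
    h0 = plant.haplotypes[0]
    haps = (Haplotype(h0.mosaic, h0.private | {(chrom, pos)}), plant.haplotypes[1])
    return replace(plant, haplotypes=haps), panel


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CausalLocus:
    """A fully penetrant recessive locus: the label is asserted iff both
    haplotypes carry the causal (alt) allele."""

    label: str
    chrom: str
    pos: int


def phenotype_of(
    plant: SimPlant, causal_loci: Sequence[CausalLocus], panel: MarkerPanel
) -> list[str]:
    labels = []
    for locus in causal_loci:
        if (locus.chrom, locus.pos) not in panel.site_index:
            raise KeyError(f"causal locus {locus.chrom}:{locus.pos} not in panel")
        if plant.dosage_at(panel, locus.chrom, locus.pos) == GT_HOM_ALT:
            labels.append(locus.label)
    return labels


# ---------------------------------------------------------------------------
# Read sampling and genotype calling
# ---------------------------------------------------------------------------

def pool_dosage(plants: Sequence[SimPlant], panel: MarkerPanel) -> np.ndarray:
    """Mean alt-allele dosage of the pool members at every panel site."""
    if len(plants) == 0:
        raise ValueError("empty pool")
    return dosage_matrix(panel, plants).mean(axis=1)


def sample_reads(
    dosage: np.ndarray,
    depth_mean: float,
    base_error: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref_count, alt_count) for dosages in [0, 2].

    Depth ~ Poisson(depth_mean); alt reads ~ Binomial(depth, p') with
    p = dosage / 2 flipped by the base error: p' = p(1-e) + (1-p)e.
    Accepts a vector (one sample) or a sites-x-samples matrix; pools pass
    their fractional mean dosage.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if not 0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    d = np.asarray(dosage, dtype=float)
    p = d / 2.0
    p_err = p * (1.0 - base_error) + (1.0 - p) * base_error
    depth = rng.poisson(depth_mean, size=d.shape)
    alt = rng.binomial(depth, p_err)
    return (depth - alt).astype(np.int32), alt.astype(np.int32)


def genotype_from_counts(
    ref_count: np.ndarray,
    alt_count: np.ndarray,
    min_depth: int = 4,
    hom_frac: float = 0.8,
) -> np.ndarray:
    """Threshold genotype caller on allele counts.

    missing if depth < min_depth; hom-alt if alt fraction >= hom_frac;
    hom-ref if <= 1 - hom_frac; else het. Returns int8 codes
    (-1 missing / 0 hom-ref / 1 het / 2 hom-alt).
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("counts must be >= 0")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    eps = 1e-9  # boundary fractions (e.g. 2/10 vs 1 - 0.8) count as homozygous
    out = np.full(np.shape(ref), GT_HET, dtype=np.int8)
    out = np.where(frac >= hom_frac - eps, GT_HOM_ALT, out)
    out = np.where(frac <= 1.0 - hom_frac + eps, GT_HOM_REF, out)
    out = np.where(depth < min_depth, GT_MISSING, out)
    return out.astype(np.int8)


def genotype_plants(
    panel: MarkerPanel,
    plants: Sequence[SimPlant],
    config: SimConfig,
    rng: np.random.Generator,
    noiseless: bool = False,
):
    """Sequence plants and call genotypes; returns a VariantTable.

    With ``noiseless=True`` the true dosage is reported as the call at
    uniform depth 30 (no read sampling)."""
    from .variant_io import VariantTable

    dos = dosage_matrix(panel, plants)
    names = [p.name for p in plants]
    if noiseless:
        gt = dos.astype(np.int8)
        alt = (dos.astype(np.int32) * 15)
        ref = (30 - alt).astype(np.int32)
    else:
        ref, alt = sample_reads(dos, config.depth_mean, config.base_error, rng)
        gt = genotype_from_counts(ref, alt, config.min_depth, config.hom_frac)
    sites = panel.df[["chrom", "pos", "ref", "alt"]].copy()
    return VariantTable(sites, names, gt, ref, alt)


# ---------------------------------------------------------------------------
# Truth extraction
# ---------------------------------------------------------------------------

def truth_regions(plant: SimPlant):
    """True donor-ancestry segments of a plant as a RegionSet with a
    zygosity label ('homozygous' where both haplotypes are donor,
    'heterozygous' where exactly one is)."""
    from .variant_io import RegionSet

    rows = []
    for chrom, length in plant.genome.chromosomes:
        seg0 = plant.haplotypes[0].mosaic.segments[chrom]
        seg1 = plant.haplotypes[1].mosaic.segments[chrom]
        bounds = np.unique(np.concatenate([seg0[:, 1], seg1[:, 1]]))
        start = 1
        for end in bounds:
            mid = np.array([start])
            a0 = plant.haplotypes[0].mosaic.ancestry_at(chrom, mid)[0]
            a1 = plant.haplotypes[1].mosaic.ancestry_at(chrom, mid)[0]
            n_donor = int(a0 == DONOR) + int(a1 == DONOR)
            if n_donor > 0:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(start),
                        "end": int(end),
                        "label": "homozygous" if n_donor == 2 else "heterozygous",
                    }
                )
            start = int(end) + 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    # merge touching rows with equal zygosity
    merged = []
    for row in df.itertuples(index=False):
        if (
            merged
            and merged[-1]["chrom"] == row.chrom
            and merged[-1]["label"] == row.label
            and merged[-1]["end"] + 1 == row.start
        ):
            merged[-1]["end"] = row.end
        else:
            merged.append(dict(row._asdict()))
    return RegionSet(pd.DataFrame(merged, columns=["chrom", "start", "end", "label"]))


# ---------------------------------------------------------------------------
# Pedigree specification and runner
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Declarative crossing / selfing / tissue-culture history.

    Events (dicts with an ``op`` key) are executed in order; every event's
    inputs must name previously defined plants:

    - ``founders``: donor_density, parent2_density -> plants
      'recipient', 'donor', 'parent2'
    - ``cross``: p1, p2, child
    - ``self``: parent, child, generations (default 1; single-seed descent)
    - ``self_family``: parent, children (list of names)
    - ``self_until``: parent, child, and a condition — ``phenotype``
      ("label" or "not:label") and/or ``dosage_at`` ([[chrom, pos, d], ...]);
      offspring are drawn until one matches (max_tries, default 200),
      modelling the field selection of plants showing a trait
    - ``tissue_culture``: parent, child, tdna: [chrom, pos]
    - ``f2_population``: p1, p2, size, prefix
    - ``pool``: name, from_prefix, size, phenotype ("label" / "not:label")
    """

    events: list[dict]
    causal_loci: list[CausalLocus] = field(default_factory=list)


@dataclass
class PedigreeResult:
    genome: GenomeSpec
    panel: MarkerPanel
    plants: dict[str, SimPlant]
    pools: dict[str, list[str]]
    phenotypes: dict[str, list[str]]
    config: SimConfig

    def phenotype(self, name: str) -> list[str]:
        return self.phenotypes[name]


def run_pedigree(
    spec: PedigreeSpec, config: SimConfig, genome: GenomeSpec | None = None
) -> PedigreeResult:
    """Execute a PedigreeSpec deterministically under config.seed."""
    genome = genome or GenomeSpec.default()
    rng = config.rng()
    lam = config.crossover_lambda
    plants: dict[str, SimPlant] = {}
    pools: dict[str, list[str]] = {}
    panel: MarkerPanel | None = None

    def get(name: str) -> SimPlant:
        if name not in plants:
            raise ValueError(f"pedigree references undefined plant {name!r}")
        return plants[name]

    for event in spec.events:
        op = event.get("op")
        if op == "founders":
            panel, rec, don, p2 = make_founders(
                genome, event["donor_density"], event.get("parent2_density", 0.0), rng
            )
            for chrom, pos, mclass in event.get("extra_markers", []):
                if (chrom, int(pos)) not in panel.site_index:
                    panel = panel.with_markers(
                        pd.DataFrame(
                            [{"chrom": chrom, "pos": int(pos), "ref": "C",
                              "alt": "A", "mclass": mclass}]
                        )
                    )
            plants.update({"recipient": rec, "donor": don, "parent2": p2})
        elif op == "cross":
            plants[event["child"]] = replace(
                cross(get(event["p1"]), get(event["p2"]), lam, rng), name=event["child"]
            )
        elif op == "self":
            child = get(event["parent"])
            for _ in range(event.get("generations", 1)):
                child = self_plant(child, lam, rng)
            plants[event["child"]] = replace(child, name=event["child"])
        elif op == "self_family":
            parent = get(event["parent"])
            for name in event["children"]:
                plants[name] = replace(self_plant(parent, lam, rng), name=name)
        elif op == "self_until":
            parent = get(event["parent"])
            want = event.get("phenotype")
            dosage_at = event.get("dosage_at", [])
            for _ in range(event.get("max_tries", 200)):
                cand = self_plant(parent, lam, rng)
                ok = True
                if want is not None:
                    labels = phenotype_of(cand, spec.causal_loci, panel)
                    ok = (want[4:] not in labels) if want.startswith("not:") else (want in labels)
                for chrom, pos, d in dosage_at:
                    ok = ok and cand.dosage_at(panel, chrom, int(pos)) == d
                if ok:
                    break
            else:
                raise ValueError(
                    f"self_until for {event['child']!r}: no matching offspring"
                )
            plants[event["child"]] = replace(cand, name=event["child"])
        elif op == "tissue_culture":
            plant = get(event["parent"])
            plant, panel = apply_culture_mutations(
                plant, config.culture_mutation_rate, rng, panel
            )
            if "tdna" in event:
                chrom, pos = event["tdna"]
                plant, panel = insert_tdna(plant, chrom, int(pos), panel)
            if "extra_mutations" in event:
                # deterministic, named culture mutations (e.g. a causal site)
                for chrom, pos in event["extra_mutations"]:
                    panel = panel.with_markers(
                        pd.DataFrame(
                            [
                                {
                                    "chrom": chrom,
                                    "pos": int(pos),
                                    "ref": "G",
                                    "alt": "A",
                                    "mclass": CULTURE_MUTATION,
                                }
                            ]
                        )
                    )
                    i = int(rng.integers(2))
                    h = plant.haplotypes[i]
                    haps = list(plant.haplotypes)
                    haps[i] = Haplotype(h.mosaic, h.private | {(chrom, int(pos))})
                    plant = replace(plant, haplotypes=tuple(haps))
            plants[event["child"]] = replace(plant, name=event["child"])
        elif op == "f2_population":
            p1, p2 = get(event["p1"]), get(event["p2"])
            f1 = cross(p1, p2, lam, rng, "f1")
            for i in range(event["size"]):
                name = f"{event['prefix']}{i+1:04d}"
                plants[name] = replace(self_plant(f1, lam, rng), name=name)
        elif op == "pool":
            prefix = event["from_prefix"]
            want = event.get("phenotype")
            members = []
            for name, plant in plants.items():
                if not name.startswith(prefix):
                    continue
                labels = phenotype_of(plant, spec.causal_loci, panel)
                if want is None:
                    ok = True
                elif want.startswith("not:"):
                    ok = want[4:] not in labels
                else:
                    ok = want in labels
                if ok:
                    members.append(name)
                if len(members) == event["size"]:
                    break
            if len(members) < event["size"]:
                raise ValueError(
                    f"pool {event['name']!r}: only {len(members)} matching plants"
                )
            pools[event["name"]] = members
        else:
            raise ValueError(f"unknown pedigree op {op!r}")

    if panel is None:
        raise ValueError("pedigree defined no founders")
    phenotypes = {
        name: phenotype_of(p, spec.causal_loci, panel) for name, p in plants.items()
    }
    return PedigreeResult(genome, panel, plants, pools, phenotypes, config)


# ---------------------------------------------------------------------------
# Study presets and scenario builders
# ---------------------------------------------------------------------------

def m0028590_pedigree(
    genome: GenomeSpec | None = None,
    donor_density: float = 1e-3,
    parent2_density: float = 1e-4,
    causal_grain: tuple[str, int] | None = None,
    causal_dwarf: tuple[str, int] | None = None,
    tdna: tuple[str, int] | None = None,
    f2_size: int = 120,
    pool_size: int = 20,
) -> PedigreeSpec:
    """Pedigree mimicking the study line: one spontaneous outcross of the
    recipient by an indica-like donor, one selfing, tissue culture with
    T-DNA insertion and a causal de-novo mutation, then three selfing
    generations (T1-T3) and an F2 mapping population crossed to a second
    japonica-like parent.

    The grain-size causal allele rides on the donor haplotype; the dwarf
    causal allele is a tissue-culture mutation.
    """
    genome = genome or GenomeSpec.default()
    causal_grain = causal_grain or (genome.names[2], genome.lengths[genome.names[2]] // 2)
    causal_dwarf = causal_dwarf or (genome.names[3], 2 * genome.lengths[genome.names[3]] // 3)
    tdna = tdna or (genome.names[2 % len(genome.names)], genome.lengths[genome.names[0]] // 3)
    events = [
        {
            "op": "founders",
            "donor_density": donor_density,
            "parent2_density": parent2_density,
            "extra_markers": [[causal_grain[0], causal_grain[1], DONOR_DIAGNOSTIC]],
        },
        # clean recipient-derived lines used as detector controls
        {"op": "self_family", "parent": "recipient", "children": ["ctrl1", "ctrl2"]},
        {"op": "cross", "p1": "recipient", "p2": "donor", "child": "F1"},
        {"op": "self", "parent": "F1", "child": "F2_seed"},
        {
            "op": "tissue_culture",
            "parent": "F2_seed",
            "child": "T0",
            "tdna": list(tdna),
            "extra_mutations": [list(causal_dwarf)],
        },
        # field selection: the study line was chosen because its offspring
        # showed the traits, so sibling draws are conditioned accordingly
        {"op": "self", "parent": "T0", "child": "T1a"},
        {
            "op": "self_until",
            "parent": "T0",
            "child": "T1b",
            "dosage_at": [[causal_dwarf[0], causal_dwarf[1], 1]],
        },
        {
            "op": "self_until",
            "parent": "T0",
            "child": "T1c",
            "phenotype": "tillering-dwarf",
        },
        {
            "op": "self_until",
            "parent": "T1b",
            "child": "T2a",
            "phenotype": "not:tillering-dwarf",
        },
        {
            "op": "self_until",
            "parent": "T1b",
            "child": "T2b",
            "phenotype": "tillering-dwarf",
        },
        {"op": "self_family", "parent": "T2b", "children": ["T3a", "T3b"]},
        {"op": "f2_population", "p1": "donor", "p2": "parent2", "size": f2_size, "prefix": "F2_"},
        {
            "op": "pool",
            "name": "pool_mutant",
            "from_prefix": "F2_",
            "size": pool_size,
            "phenotype": "large-grain",
        },
        {
            "op": "pool",
            "name": "pool_wildtype",
            "from_prefix": "F2_",
            "size": pool_size,
            "phenotype": "not:large-grain",
        },
    ]
    causal_loci = [
        CausalLocus("large-grain", *causal_grain),
        CausalLocus("tillering-dwarf", *causal_dwarf),
    ]
    return PedigreeSpec(events, causal_loci)


@dataclass
class BsaSimResult:
    """Pooled allele counts of a simulated bulk-segregant experiment."""

    genome: GenomeSpec
    panel: MarkerPanel
    causal: CausalLocus
    counts: pd.DataFrame  # chrom, pos, ref/alt counts for each pool
    n_f2: int
    phenotype_fraction_mutant: float


def simulate_bsa_experiment(
    seed: int,
    genome: GenomeSpec | None = None,
    marker_density: float | None = None,
    n_f2: int = 1000,
    pool_size: int = 20,
    depth_mean: float = 15.0,
    base_error: float = 0.005,
    crossover_lambda: float = 1.25,
    causal_cluster_spacing: int | None = 100,
    causal_cluster_n: int = 40,
) -> BsaSimResult:
    """Simulate the mapping experiment behind SNP-index BSA.

    An F2 population segregating ~``marker_density * genome`` biallelic
    markers is generated from a cross of two inbred parents; one marker is a
    fully penetrant recessive causal locus carried by the alternate-allele
    (mutant) parent. Two DNA pools of ``pool_size`` plants each — phenotypic
    mutants (homozygous recessive) and phenotypic wild types — are sequenced
    at the given mean depth, returning pooled allele counts per marker.

    ``causal_cluster_spacing`` adds ``causal_cluster_n`` extra markers at
    fixed spacing around the causal site, reproducing the dense local marker
    spacing (~1 SNP per 100-150 bp) of a real indica/japonica contrast that
    the sparse desk-scale panel otherwise lacks.
    """
    genome = genome or GenomeSpec.default()
    if marker_density is None:
        marker_density = 5000 / genome.total_bp
    rng = np.random.default_rng(seed)
    panel, recipient, donor, _ = make_founders(genome, marker_density, 0.0, rng)

    causal_chrom = genome.names[len(genome.names) // 2]
    causal_pos = genome.lengths[causal_chrom] // 2
    if causal_cluster_spacing:
        half = causal_cluster_n // 2
        cluster = [
            causal_pos + causal_cluster_spacing * k
            for k in range(-half, half + 1)
            if k != 0
        ]
        taken = panel.site_index
        rows = [
            {"chrom": causal_chrom, "pos": p, "ref": "C", "alt": "A",
             "mclass": DONOR_DIAGNOSTIC}
            for p in cluster
            if (causal_chrom, p) not in taken
        ]
        panel = panel.with_markers(pd.DataFrame(rows))
    if (causal_chrom, causal_pos) not in panel.site_index:
        panel = panel.with_markers(
            pd.DataFrame(
                [{"chrom": causal_chrom, "pos": causal_pos, "ref": "C", "alt": "A",
                  "mclass": DONOR_DIAGNOSTIC}]
            )
        )
    causal = CausalLocus("mutant", causal_chrom, causal_pos)

    f1 = cross(recipient, donor, crossover_lambda, rng, "f1")
    causal_row = panel.locus_row(causal_chrom, causal_pos)

    mutant_members: list[SimPlant] = []
    wildtype_members: list[SimPlant] = []
    n_mutant_pheno = 0
    for i in range(n_f2):
        plant = self_plant(f1, crossover_lambda, rng, f"F2_{i+1:04d}")
        is_mutant = plant.dosage_at(panel, causal_chrom, causal_pos) == 2
        n_mutant_pheno += is_mutant
        if is_mutant and len(mutant_members) < pool_size:
            mutant_members.append(plant)
        elif not is_mutant and len(wildtype_members) < pool_size:
            wildtype_members.append(plant)
    if len(mutant_members) < pool_size or len(wildtype_members) < pool_size:
        raise ValueError("F2 population too small to fill both pools")

    counts = panel.df[["chrom", "pos"]].copy()
    for label, members in (("mutant", mutant_members), ("wildtype", wildtype_members)):
        dos = pool_dosage(members, panel)
        ref, alt = sample_reads(dos, depth_mean, base_error, rng)
        counts[f"ref_{label}"] = ref
        counts[f"alt_{label}"] = alt
    _ = causal_row
    return BsaSimResult(
        genome, panel, causal, counts, n_f2, n_mutant_pheno / n_f2
    )
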