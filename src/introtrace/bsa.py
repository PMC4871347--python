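"""Bulk-segregant SNP-index mapping from pooled allele counts.

The SNP index of a DNA pool at a marker is the pooled alternate-allele read
fraction (mutant reads / total reads). Away from a causal locus an F2 pool's
index fluctuates around 0.5; at a fully penetrant recessive locus the
phenotypically mutant pool is fixed for the mutant allele (index 1), while
the phenotypic wild-type pool — 1 AA : 2 Aa — expects 1/3. Tracks are
smoothed with a moving window of 20 consecutive defined markers shifted one
marker at a time, and peaks are called where the mutant pool's smoothed
index stays high while the wild-type pool's stays moderate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import RegionSet

logger = logging.getLogger(__name__)

# Window anchor convention: midpoint of the first and last marker of the
# window. Recorded in track metadata so exports are self-describing.
ANCHOR_CONVENTION = "midpoint(first_marker, last_marker)"


@dataclass
class SnpIndexTrack:
    """Per-marker pooled allele-frequency index plus optional smoothed
    windows.

    ``markers``: chrom, pos, alt_count, total_count, index (NaN where the
    total is below the depth floor). ``windows``: chrom, anchor, start, end,
    value, n (only present after smoothing).
    """

    pool: str
    markers: pd.DataFrame
    windows: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def defined(self) -> pd.DataFrame:
        return self.markers[~self.markers["index"].isna()]


def snp_index(
    counts: pd.DataFrame,
    pool: str,
    ref_col: str | None = None,
    alt_col: str | None = None,
    min_depth: int = 5,
) -> SnpIndexTrack:
    """Raw per-marker SNP index alt/(ref+alt) for one pool.

    ``counts`` must carry chrom, pos and the pool's ref/alt count columns
    (default names ``ref_<pool>`` / ``alt_<pool>``). Markers with total
    depth below ``min_depth`` get an undefined (NaN) index."""
    ref_col = ref_col or f"ref_{pool}"
    alt_col = alt_col or f"alt_{pool}"
    for col in ("chrom", "pos", ref_col, alt_col):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    ref = counts[ref_col].to_numpy()
    alt = counts[alt_col].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("counts must be >= 0")
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    idx = np.where(total < min_depth, np.nan, idx)
    markers = pd.DataFrame(
        {
            "chrom": counts["chrom"],
            "pos": counts["pos"],
            "alt_count": alt,
            "total_count": total,
            "index": idx,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SnpIndexTrack(pool, markers, meta={"min_depth": min_depth})


def harmonize(a: SnpIndexTrack, b: SnpIndexTrack) -> tuple[SnpIndexTrack, SnpIndexTrack]:
    """Restrict two raw tracks to the markers defined in both, so their
    smoothed windows align one-to-one."""
    key = ["chrom", "pos"]
    da, db = a.defined(), b.defined()
    shared = da[key].merge(db[key], on=key)
    out = []
    for t, d in ((a, da), (b, db)):
        m = d.merge(shared, on=key).reset_index(drop=True)
        out.append(SnpIndexTrack(t.pool, m, meta=dict(t.meta)))
    return out[0], out[1]


def smooth_track(
    raw: SnpIndexTrack, window_snps: int = 20, step_snps: int = 1
) -> SnpIndexTrack:
    """Moving-window mean over consecutive *defined* markers, per
    chromosome; a chromosome with fewer defined markers than the window
    yields no smoothed values. Each window is anchored at the midpoint of
    its first and last marker positions."""
    if window_snps < 1 or step_snps < 1:
        raise ValueError("window_snps and step_snps must be >= 1")
    frames = []
    for chrom, sub in raw.defined().groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub["index"].to_numpy()
        n = len(idx)
        if n < window_snps:
            logger.warning(
                "pool %s: chromosome %s has %d defined markers < window %d; "
                "no smoothed values",
                raw.pool, chrom, n, window_snps,
            )
            continue
        csum = np.concatenate([[0.0], np.cumsum(idx)])
        starts = np.arange(0, n - window_snps + 1, step_snps)
        values = (csum[starts + window_snps] - csum[starts]) / window_snps
        first = pos[starts]
        last = pos[starts + window_snps - 1]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "anchor": (first + last) // 2,
                    "start": first,
                    "end": last,
                    "value": values,
                    "n": window_snps,
                }
            )
        )
    windows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "anchor", "start", "end", "value", "n"])
    )
    meta = dict(raw.meta)
    meta.update(
        window_snps=window_snps, step_snps=step_snps, anchor=ANCHOR_CONVENTION
    )
    return SnpIndexTrack(raw.pool, raw.markers, windows, meta)


def _check_aligned(mutant: SnpIndexTrack, wildtype: SnpIndexTrack) -> None:
    for t in (mutant, wildtype):
        if t.windows is None:
            raise ValueError(f"track {t.pool!r} has no smoothed windows")
    a, b = mutant.windows, wildtype.windows
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["anchor"].to_numpy() == b["anchor"].to_numpy()).all()
    ):
        raise ValueError(
            "tracks are not on the same marker set; harmonize() the raw tracks first"
        )


def call_peak_regions(
    mutant: SnpIndexTrack,
    wildtype: SnpIndexTrack,
    high: float = 0.9,
    control_max: float = 0.7,
    min_windows: int = 5,
) -> RegionSet:
    """Candidate causal regions: maximal runs of at least ``min_windows``
    consecutive windows where the mutant pool's smoothed index is >= high
    and the wild-type pool's is <= control_max; each run becomes the
    genomic interval from its first to its last window anchor."""
    _check_aligned(mutant, wildtype)
    rows = []
    mw, ww = mutant.windows, wildtype.windows
    for chrom in pd.unique(mw["chrom"]):
        sel = (mw["chrom"] == chrom).to_numpy()
        mv = mw["value"].to_numpy()[sel]
        wv = ww["value"].to_numpy()[sel]
        anchors = mw["anchor"].to_numpy()[sel]
        hit = (mv >= high) & (wv <= control_max)
        if not hit.any():
            continue
        idx = np.flatnonzero(hit)
        run_start = prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i == prev + 1:
                prev = i
                continue
            runs.append((run_start, prev))
            run_start = prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            if b - a + 1 >= min_windows:
                rows.append((chrom, int(anchors[a]), int(anchors[b])))
    if not rows:
        return RegionSet.empty()
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def delta_index(mutant: SnpIndexTrack, wildtype: SnpIndexTrack) -> pd.DataFrame:
    """Per-window difference mutant - wildtype (the QTL-seq delta-index
    companion statistic)."""
    _check_aligned(mutant, wildtype)
    out = mutant.windows[["chrom", "anchor", "start", "end"]].copy()
    out["delta"] = mutant.windows["value"].to_numpy() - wildtype.windows["value"].to_numpy()
    return out


def mean_index_off_target(track: SnpIndexTrack, exclude_chrom: str) -> tuple[float, int]:
    """Mean smoothed index over chromosomes other than ``exclude_chrom``
    (the genome-wide neutrality summary), with the window count."""
    if track.windows is None:
        raise ValueError("track has no smoothed windows")
    sub = track.windows[track.windows["chrom"] != exclude_chrom]
    return float(sub["value"].mean()), int(len(sub))
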