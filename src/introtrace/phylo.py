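"""Allele-sharing distances and a neighbor-joining SNP phylogeny.

The point being tested is clustering: restricted to an introgressed region,
an outcrossed offspring should group with the donor (indica-like) samples,
while on the whole genome it groups with the recipient (japonica-like)
background. An allele-sharing (dosage) distance supports that contrast at
desk scale without a maximum-likelihood pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .variant_io import GT_MISSING, RegionSet, VariantTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise allele-sharing distances in [0, 1] with the
    per-pair informative-site counts."""

    labels: list[str]
    matrix: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def allele_sharing_distance(
    table: VariantTable,
    samples: Sequence[str],
    region: RegionSet | None = None,
    min_sites: int = 100,
) -> DistanceMatrix:
    """Mean per-site dosage distance |d_i - d_j| / 2 over sites genotyped in
    both samples (pairwise deletion), within ``region`` if given. A pair
    sharing fewer than ``min_sites`` genotyped SNP sites is an error."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    idx = [table.sample_index(s) for s in samples]
    keep = table.snp_mask()
    if region is not None:
        in_region = np.zeros(table.n_sites, dtype=bool)
        for row in region.df.itertuples(index=False):
            rows = table.site_rows(row.chrom, int(row.start), int(row.end))
            in_region[rows] = True
        keep &= in_region
    gt = table.gt[keep][:, idx].astype(float)
    gt[gt == GT_MISSING] = np.nan
    n = len(samples)
    dist = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    bad_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(gt[:, i]) & ~np.isnan(gt[:, j])
            counts[i, j] = counts[j, i] = int(both.sum())
            if counts[i, j] < min_sites:
                bad_pairs.append((samples[i], samples[j], counts[i, j]))
                continue
            d = float(np.abs(gt[both, i] - gt[both, j]).mean() / 2.0)
            dist[i, j] = dist[j, i] = d
    if bad_pairs:
        raise ValueError(f"pairs below min_sites={min_sites}: {bad_pairs}")
    return DistanceMatrix(list(samples), dist, counts)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor-joining agglomeration (Saitou & Nei, Studier &
    Keppler Q-criterion). Ties are broken by the smallest (i, j) pair so the
    result is deterministic; negative branch lengths are clamped to zero
    with the deficit logged. Returns an unrooted tree represented with a
    trifurcating root for n >= 3 taxa."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=label) for label in dm.labels]

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li)
        b.length = clamp(lj)
        parent.extend([a, b])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the last three nodes with the closed-form three-point formulas
    (x, y, z) = nodes
    dxy, dxz, dyz = d[0, 1], d[0, 2], d[1, 2]
    x.length = clamp(0.5 * (dxy + dxz - dyz))
    y.length = clamp(0.5 * (dxy + dyz - dxz))
    z.length = clamp(0.5 * (dxz + dyz - dxy))
    root = TreeNode()
    root.extend([x, y, z])
    return root


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def placement_check(
    tree: TreeNode,
    focal_samples: Sequence[str],
    donor_group: Sequence[str],
    recipient_group: Sequence[str],
) -> dict[str, str]:
    """Assign each focal leaf to 'donor' or 'recipient': on the
    midpoint-rooted tree, walk up from the focal leaf and use the first
    enclosing clade containing reference leaves; the group with the
    majority of reference leaves in that clade wins (ties walk further up).
    """
    tree = tree.copy()
    try:
        rooted = tree.root_at_midpoint()
    except Exception:  # zero-length degenerate trees
        rooted = tree
    leaf_names = {t.name for t in rooted.tips()}
    for group in (donor_group, recipient_group):
        missing = set(group) - leaf_names
        if missing:
            raise ValueError(f"group leaves not in tree: {sorted(missing)}")
    donor_set, recip_set = set(donor_group), set(recipient_group)
    out = {}
    for focal in focal_samples:
        if focal not in leaf_names:
            raise ValueError(f"focal sample {focal!r} not a leaf")
        node = rooted.find(focal)
        assigned = None
        while node.parent is not None:
            node = node.parent
            names = {t.name for t in node.tips()} - {focal}
            nd = len(names & donor_set)
            nr = len(names & recip_set)
            if nd > nr:
                assigned = "donor"
                break
            if nr > nd:
                assigned = "recipient"
                break
        out[focal] = assigned or "unresolved"
    return out
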