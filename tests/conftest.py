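import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from introtrace import sim_cross as sc

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from introtrace.variant_io import VariantTable


@pytest.fixture
def small_genome():
    """One 2.5-Mb chromosome — enough for marker-level genetics."""
    return sc.GenomeSpec((("chr01", 2_500_000),))


@pytest.fixture
def desk_genome():
    return sc.GenomeSpec.default(n_chromosomes=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def founders(desk_genome, rng):
    panel, recipient, donor, parent2 = sc.make_founders(desk_genome, 1e-3, 1e-4, rng)
    return panel, recipient, donor, parent2


def make_table(records, samples):
    """Build a VariantTable from (chrom, pos, ref, alt, [gt per sample]) rows.

    Allele depths are synthesised as clean depth-20 counts consistent with
    each genotype (missing -> zero depth)."""
    sites = pd.DataFrame(
        [r[:4] for r in records], columns=["chrom", "pos", "ref", "alt"]
    )
    gt = np.array([r[4] for r in records], dtype=np.int8)
    alt_d = np.where(gt < 0, 0, gt * 10).astype(np.int32)
    ref_d = np.where(gt < 0, 0, 20 - gt * 10).astype(np.int32)
    return VariantTable(sites, list(samples), gt, ref_d, alt_d)
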