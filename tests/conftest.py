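import numpy as np
import pandas as pd
import pytest

from foltile.rrbs_io import SampleMethylome
from foltile.synthetic_data import SimConfig


@pytest.fixture
def tiny_cfg():
    """Desk-scale config: one 100 kb chromosome, two diets, one tissue."""
    return SimConfig(seed=11, n_chroms=1, chrom_len=100_000,
                     diets=("Ctrl", "20FS"), tissues=("placenta",))


def make_sample(sample_id, tissue, diet, rows, sex="unknown"):
    """Build a SampleMethylome from (chrom, pos, meth, unmeth) tuples."""
    rec = pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_unmeth"])
    rec = rec.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SampleMethylome(sample_id, tissue, diet, sex, rec)


@pytest.fixture
def two_group_samples():
    """3 vs 3 samples over two tiles of chr1 with a clear group difference.

    Tile [0, 100): 3 CpGs, control ~20% methylated, treated ~80%.
    Tile [100, 200): 2 CpGs, both groups ~50%.
    """
    def counts(p, cov=20):
        m = int(round(cov * p))
        return m, cov - m
    samples = []
    for i in range(3):
        rows = [("chr1", 11, *counts(0.2)), ("chr1", 41, *counts(0.2)),
                ("chr1", 71, *counts(0.25)),
                ("chr1", 111, *counts(0.5)), ("chr1", 151, *counts(0.5))]
        samples.append(make_sample(f"c{i}", "placenta", "Ctrl", rows))
    for i in range(3):
        rows = [("chr1", 11, *counts(0.8)), ("chr1", 41, *counts(0.8)),
                ("chr1", 71, *counts(0.75)),
                ("chr1", 111, *counts(0.5)), ("chr1", 151, *counts(0.55))]
        samples.append(make_sample(f"t{i}", "placenta", "20FS", rows))
    return samples
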