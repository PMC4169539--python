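import numpy as np
import pytest

from eurostruct.io import MISSING, GenotypeDataset, GeoPanel, SnpRecord
from eurostruct.sim import SimConfig


def make_snps(n, per_chrom=None, spacing=10_000):
    """Simple SNP map: ids s000..., one chromosome unless per_chrom given."""
    per_chrom = per_chrom or n
    return [
        SnpRecord(f"s{j:04d}", str(j // per_chrom + 1), (j % per_chrom) * spacing + 1, "G", "A")
        for j in range(n)
    ]


def make_dataset(dosages, populations, snps=None, ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    return GenotypeDataset(
        dosages,
        ids or [f"i{k}" for k in range(n)],
        snps or make_snps(s),
        list(populations),
    )


def two_pop_config(n_per_pop=100, n_snps=1000, f=0.01, seed=1, km_apart=0.0, **kw):
    """Two populations, optionally separated north-south by km_apart."""
    dlat = km_apart / 111.19 / 2
    geo = GeoPanel.from_dict({"A": (50 + dlat, 5.0), "B": (50 - dlat, 5.0)})
    return SimConfig(
        populations=["A", "B"],
        samples_per_pop=[n_per_pop, n_per_pop],
        n_snps=n_snps,
        fst_per_pop=[f, f],
        geo=geo,
        seed=seed,
        **kw,
    )


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, size=(12, 8)).astype(np.int8)
    d[0, 1] = MISSING
    d[5, 3] = MISSING
    return make_dataset(d, ["P1"] * 6 + ["P2"] * 6)
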