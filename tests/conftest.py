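import numpy as np
import pandas as pd
import pytest

from trisexscan.model import CrossSpec, genotype
from trisexscan.simulate import SimConfig, simulate_family

# small two-chromosome genome used by tests that loop over seeds
FAST_CHROMS = (("Chr1", 150_000_000), ("Chr7", 133_565_930))


@pytest.fixture(scope="session")
def fast_config():
    return SimConfig(seed=0, chromosomes=FAST_CHROMS)


@pytest.fixture(scope="session")
def default_family(fast_config):
    """One deterministic WZ x WY family shared by read-only tests."""
    return simulate_family(fast_config, seed=101)


@pytest.fixture(scope="session")
def clean_family():
    """Error-free, complete family for exact Mendelian/linkage checks."""
    cfg = SimConfig(seed=0, chromosomes=FAST_CHROMS,
                    het_to_hom_error_rate=0.0, missing_rate=0.0,
                    depth_mean_offspring=60.0, depth_mean_parents=240.0)
    return simulate_family(cfg, seed=7)


def make_family_dataset(gt, chrom="Chr1", positions=None, radtags=None,
                        dp=None, gq=None, offspring_sexes=None):
    """Hand-built FamilyDataset: gt is sites x (mother, father, offspring...)."""
    from trisexscan.simulate import FamilyDataset

    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    n_off = n_ind - 2
    ids = ["mom", "dad"] + [f"o{i}" for i in range(n_off)]
    sexes = ["female", "male"] + list(
        offspring_sexes if offspring_sexes is not None
        else ["female", "male"] * n_off
    )[: n_ind]
    ped = pd.DataFrame({
        "id": ids, "family": "f", "role": ["mother", "father"] + ["offspring"] * n_off,
        "sex": sexes[:n_ind],
    })
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": positions if positions is not None else np.arange(1, n_sites + 1) * 1000,
        "radtag": radtags if radtags is not None else [f"t{i}" for i in range(n_sites)],
    })
    dp = np.full(gt.shape, 50, dtype=np.int32) if dp is None else np.asarray(dp, dtype=np.int32)
    gq = np.full(gt.shape, 99, dtype=np.int16) if gq is None else np.asarray(gq, dtype=np.int16)
    return FamilyDataset(ped, ids, sites, gt, dp, gq)
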