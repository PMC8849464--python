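import numpy as np
import pandas as pd
import pytest

from landgen.datatypes import GenotypeMatrix


def build_gm(geno, sites, ecotopes=None, years=None, coords=None):
    """GenotypeMatrix from plain lists; coordinates default to distinct x."""
    geno = np.asarray(geno, dtype=np.int8)
    n = geno.shape[0]
    if ecotopes is None:
        ecotopes = ["domestic"] * n
    if years is None:
        years = [2016] * n
    if coords is None:
        coords = [(float(i) * 100.0, 0.0) for i in range(n)]
    meta = pd.DataFrame(
        {
            "site_id": sites,
            "ecotope": ecotopes,
            "year": years,
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
        },
        index=[f"s{i}" for i in range(n)],
    )
    return GenotypeMatrix(
        geno,
        list(meta.index),
        [f"L{j}" for j in range(geno.shape[1])],
        meta,
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """A mid-sized synthetic dataset with injected outlier loci, shared
    across tests that only read it."""
    from landgen.synthetic import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_sites=12,
        n_dual_sites=6,
        samples_per_site=8,
        n_loci=300,
        n_outlier_loci=5,
        ecotope_shift=2.0,
        grid_shape=(40, 40),
        baseline_fst=0.1,
        missing_rate=0.005,
        seed=42,
    )
    return cfg, simulate_dataset(cfg)
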