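import numpy as np
import pandas as pd
import pytest

from invkaryo import simulate as sim
from invkaryo.types import GenotypeMatrix


def make_gm(alt_counts, positions=None, chrom="2R", gq=None, samples=None):
    """Build a small GenotypeMatrix from a raw array (rows = samples)."""
    alt_counts = np.asarray(alt_counts)
    n, m = alt_counts.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    bases = ["A", "C", "G", "T"]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": [bases[j % 4] for j in range(m)],
            "alt": [bases[(j + 1) % 4] for j in range(m)],
        }
    )
    return GenotypeMatrix(samples=samples, sites=sites, alt_counts=alt_counts, gq=gq)


@pytest.fixture(scope="session")
def clean_cohort():
    """A clean (artifact-free) single-population cohort with truth labels."""
    params = sim.SimParams(
        populations=[sim.Population("p1", "gambiae", 150, 0.4)],
        n_sites_inversion=500,
        n_sites_flank=100,
        frac_fixed_diff=0.05,
        seed=11,
    )
    gm, truth, meta = sim.simulate_cohort(params)
    return gm, truth, meta, sim.inversion_def(params)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Same structure with realistic genotyping artifacts switched on."""
    params = sim.SimParams(
        populations=[sim.Population("p1", "gambiae", 150, 0.4)],
        n_sites_inversion=500,
        n_sites_flank=100,
        frac_fixed_diff=0.05,
        error_rate=0.02,
        missing_rate=0.05,
        seed=12,
    )
    gm, truth, meta = sim.simulate_cohort(params)
    return gm, truth, meta, sim.inversion_def(params)
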