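import numpy as np
import pytest

from canidclock.io_formats import SiteKey
from canidclock.matrix_builder import FrequencyMatrix
from canidclock.synthetic_data import SimConfig, sample_cohort, simulate_counts


def make_freq(F, confident=None, observed=None, assembly="canFam3"):
    """FrequencyMatrix from a plain array, with sensible default masks."""
    F = np.asarray(F, dtype=float)
    observed = ~np.isnan(F) if observed is None else np.asarray(observed, bool)
    confident = observed if confident is None else np.asarray(confident, bool)
    sites = [SiteKey(assembly, "chr1", 100 + i) for i in range(F.shape[0])]
    samples = [f"s{j:03d}" for j in range(F.shape[1])]
    return FrequencyMatrix(sites, samples, F, confident, observed)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded two-species cohort used by several test modules."""
    cfg = SimConfig(seed=11, n_sites=800)
    meta = sample_cohort(cfg)
    counts, truth = simulate_counts(meta, cfg)
    return cfg, meta, counts, truth
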