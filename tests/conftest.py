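import numpy as np
import pytest

from breedid.genotype_io import AlleleFrequencyTable, SnpMeta
from breedid.synthetic import SimulationConfig, simulate_breed_frequencies, simulate_genotypes


def make_snps(n, chrom="1", start=1000, step=1000):
    return [SnpMeta(f"s{j+1}", chrom, start + j * step, "A", "C") for j in range(n)]


def random_freq_table(k, n_snps, seed):
    rng = np.random.default_rng(seed)
    return AlleleFrequencyTable(
        [f"B{i+1}" for i in range(k)], make_snps(n_snps), rng.uniform(0, 1, (k, n_snps))
    )


@pytest.fixture
def small_dataset():
    """3 well-separated breeds, 400 SNPs, 20 train + 10 test per breed."""
    cfg = SimulationConfig(n_breeds=3, n_snps=400, drift=0.2, seed=7)
    freqs = simulate_breed_frequencies(cfg)
    counts_train = {b: 20 for b in cfg.breed_names}
    counts_test = {b: 10 for b in cfg.breed_names}
    ref, ref_labels = simulate_genotypes(freqs, counts_train, seed=8, id_prefix="R")
    test, test_labels = simulate_genotypes(freqs, counts_test, seed=9, id_prefix="T")
    return freqs, ref, ref_labels, test, test_labels
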