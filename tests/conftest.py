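"""Shared fixtures: a small simulated trio reused across test modules."""

import pytest

from triobin import kmer_binning as kb
from triobin import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    # 2 x 300 kb trio, elevated heterozygosity so hap-mer density stays
    # informative at this scale; error-free long reads
    return sim.SimConfig(
        seed=7, n_chroms=2, chrom_len=300_000, snp_rate=2e-3, indel_rate=3e-4,
        short_coverage=20, long_coverage=20, long_error=0.0,
    )


@pytest.fixture(scope="session")
def small_trio(small_config):
    hap_a, hap_b, truth = sim.simulate_parents(small_config)
    return hap_a, hap_b, truth


@pytest.fixture(scope="session")
def small_long_reads(small_config, small_trio):
    hap_a, hap_b, truth = small_trio
    reads, truth, paf = sim.simulate_long_reads(hap_a, hap_b, small_config, truth)
    return reads, truth, paf


@pytest.fixture(scope="session")
def small_hapmers(small_config, small_trio):
    hap_a, hap_b, _ = small_trio
    ksa = kb.count_kmers(
        sim.short_read_sequences(hap_a, small_config, "A", seed_salt=21), k=21, parent_id="A"
    )
    ksb = kb.count_kmers(
        sim.short_read_sequences(hap_b, small_config, "B", seed_salt=22), k=21, parent_id="B"
    )
    return kb.extract_hapmers(ksa, ksb, min_count=5)
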