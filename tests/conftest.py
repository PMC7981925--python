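import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from svgex.model import Breakpoint, Config, GeneModel, SvRecord
from svgex.simulate import SimConfig, simulate_cohort


def make_sv(sv_id, sample, c1, p1, c2, p2, sv_type=None):
    return SvRecord(
        sv_id,
        sample,
        Breakpoint(c1, p1, sv_id, 1, sample),
        Breakpoint(c2, p2, sv_id, 2, sample),
        sv_type,
    )


def random_instance(rng, n_genes=20, n_samples=8, n_svs=60, chrom_len=5_000_000,
                    n_chroms=2):
    """Small random genes + SVs for oracle-equivalence checks."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(n_chroms) + 1}"
        start = int(rng.integers(0, chrom_len - 200_000))
        length = int(rng.integers(5_000, 150_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, start, start + length, strand))
    samples = [f"s{i}" for i in range(n_samples)]
    svs = []
    for j in range(n_svs):
        sample = samples[int(rng.integers(n_samples))]
        c1 = f"chr{rng.integers(n_chroms) + 1}"
        c2 = f"chr{rng.integers(n_chroms) + 1}"
        p1 = int(rng.integers(0, chrom_len))
        p2 = int(rng.integers(0, chrom_len))
        if c1 == c2 and p1 == p2:
            p2 = (p2 + 1) % chrom_len
        svs.append(make_sv(f"sv{j}", sample, c1, p1, c2, p2))
    return genes, samples, svs


@pytest.fixture(scope="session")
def default_config():
    return Config()


@pytest.fixture(scope="session")
def signal_cohort():
    """Moderate-size cohort with planted effects, shared across tests."""
    return simulate_cohort(
        SimConfig(n_genes=200, n_samples=80, n_svs=640, seed=7, n_fusion_pairs=20)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
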