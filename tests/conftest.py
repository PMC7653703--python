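import numpy as np
import pandas as pd
import pytest

from cnvprog.genome import GenomeSpec, ProbeMap, hg19_autosomes, generate_probe_map


@pytest.fixture(scope="session")
def genome() -> GenomeSpec:
    return hg19_autosomes()


@pytest.fixture(scope="session")
def probe_map(genome) -> ProbeMap:
    """Genome-wide map at coarse density (2,200 probes, 15% SNP)."""
    return generate_probe_map(genome, 2200, snp_fraction=0.15, seed=1)


@pytest.fixture(scope="session")
def dense_probe_map(genome) -> ProbeMap:
    """10k-probe map used for segmentation-recovery style tests."""
    return generate_probe_map(genome, 10_000, snp_fraction=0.15, seed=1)


def single_chrom_probe_map(n: int, chrom: int = 1, spacing: int = 100_000) -> ProbeMap:
    """A probe map confined to one chromosome, for per-chromosome tests."""
    pos = np.arange(1, n + 1) * spacing
    return ProbeMap(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chrom": chrom,
        "pos": pos,
        "probe_class": "CGH",
    }))
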