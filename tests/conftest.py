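"""Shared fixtures: small synthetic panels with known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popgenkit import (
    Chromosome,
    Deme,
    DemographicModel,
    GenotypePanel,
    simulate_panel,
)


def make_panel(
    genotypes: np.ndarray,
    haplotypes: np.ndarray | None = None,
    cm: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    chrom: str = "1",
    populations: list[str] | None = None,
) -> GenotypePanel:
    """Hand-build a single-chromosome panel from raw matrices."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, s = genotypes.shape
    if cm is None:
        cm = np.arange(s, dtype=float) * 0.05
    if pos is None:
        pos = (np.asarray(cm) * 1e6).astype(np.int64) + 1
        for i in range(1, s):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
    snp = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "cm": cm,
            "ref": "A",
            "alt": "T",
            "id": [f"snp{i}" for i in range(s)],
        }
    )
    pops = populations or ["pop"] * n
    st = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "population": pops,
            "major_group": pops,
            "lat": 0.0,
            "lon": 0.0,
        }
    )
    return GenotypePanel(genotypes, snp, st, haplotypes)


def complementary_pair_panel(
    n_snps: int = 3000, seed: int = 0, spacing_cm: float = 0.033
) -> GenotypePanel:
    """Two samples whose haplotypes mismatch everywhere across samples.

    Sample a carries (r1, r2); sample b carries (1-r1, 1-r2). Any planted
    copy is then the only identical stretch between the samples, making
    truth boundaries exact for detector tests.
    """
    rng = np.random.default_rng(seed)
    r1 = rng.integers(0, 2, n_snps).astype(np.int8)
    r2 = rng.integers(0, 2, n_snps).astype(np.int8)
    hap = np.array([r1, r2, 1 - r1, 1 - r2], dtype=np.int8)
    geno = hap[0::2] + hap[1::2]
    cm = np.arange(n_snps) * spacing_cm
    return make_panel(geno, hap, cm=cm, populations=["P", "P"])


@pytest.fixture(scope="session")
def two_deme_panel():
    """Two moderately diverged demes, phased, with ancestry truth."""
    model = DemographicModel(
        demes=[Deme("A", 120, bn_f=0.05), Deme("B", 120, bn_f=0.05)],
        generations=4,
        chromosomes=[Chromosome("1", 100.0, 3000)],
    )
    return simulate_panel(model, 15, seed=42)


@pytest.fixture(scope="session")
def panmictic_panel():
    """Single unstructured deme."""
    model = DemographicModel(
        demes=[Deme("P", 200)],
        generations=3,
        chromosomes=[Chromosome("1", 100.0, 2000)],
    )
    return simulate_panel(model, 24, seed=7)
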