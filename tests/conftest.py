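"""Shared fixtures: small deterministic genotype matrices and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from crediblemap.genotypes import GenotypeMatrix
from crediblemap.synthgen import AncestrySpec, simulate_haplotype_panel


def make_genotype_matrix(
    genotypes: np.ndarray,
    groups: np.ndarray | str | None = "g1",
    info_r2: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Wrap a raw genotype array with generated ids and metadata."""
    genotypes = np.asarray(genotypes, dtype=float)
    n, m = genotypes.shape
    if isinstance(groups, str):
        groups = np.full(n, groups, dtype=object)
    return GenotypeMatrix(
        genotypes=genotypes,
        variant_ids=np.array([f"snp_{j + 1}" for j in range(m)]),
        positions=np.arange(1, m + 1) * 100,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        sample_ids=np.array([f"ind_{i + 1}" for i in range(n)]),
        groups=groups,
        info_r2=info_r2,
    )


def make_spec(
    n_variants: int = 20,
    alt_freq: float | np.ndarray = 0.3,
    ld_rho: float = 0.5,
    n_cases: int = 500,
    n_controls: int = 500,
    name: str = "EU",
) -> AncestrySpec:
    freqs = np.full(n_variants, alt_freq) if np.isscalar(alt_freq) else alt_freq
    return AncestrySpec(
        name=name,
        n_variants=n_variants,
        alt_freqs=freqs,
        ld_rho=ld_rho,
        positions=np.arange(1, n_variants + 1) * 1000,
        n_cases=n_cases,
        n_controls=n_controls,
    )


@pytest.fixture(scope="session")
def hwe_panel():
    """Moderate-LD haplotype panel reused across tests (read-only)."""
    spec = make_spec(n_variants=20, alt_freq=0.3, ld_rho=0.5)
    return simulate_haplotype_panel(spec, n_hap=8000, seed=11)
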