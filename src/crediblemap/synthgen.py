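"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume, not any particular population history:

* haplotypes come from a latent Gaussian AR(1) process thresholded per site
  to hit target alternate-allele frequencies, so adjacent sites carry
  tunable linkage disequilibrium without coalescent machinery;
* case/control status follows a logistic disease model with a single causal
  variant, so the simulated per-allele odds ratio is exactly the estimand
  of the downstream logistic regression;
* admixture covariates are drawn from a 4-component Dirichlet with the
  first three components retained, mirroring the convention of using three
  of four admixture proportions as stratification covariates;
* expression panels are genotype-additive with Gaussian noise.

All randomness in a call flows from one integer seed through a single
`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit, ndtri

from .genotypes import GenotypeMatrix
from .scores import IFN_GENES, T7Bands

__all__ = [
    "AncestrySpec",
    "HaplotypePanel",
    "Cohort",
    "ExpressionMatrix",
    "simulate_haplotype_panel",
    "simulate_case_control",
    "simulate_eqtl_expression",
    "simulate_ifn_panel",
    "simulate_t7_bands",
]


@dataclass(frozen=True)
class AncestrySpec:
    """Marker map and cohort quotas for one simulated ancestral group."""

    name: str
    n_variants: int
    alt_freqs: np.ndarray
    ld_rho: float
    positions: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.alt_freqs, dtype=float)
        positions = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "alt_freqs", freqs)
        object.__setattr__(self, "positions", positions)
        if len(freqs) != self.n_variants:
            raise ValueError("alt_freqs length must equal n_variants")
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            raise ValueError("alt_freqs must lie strictly in (0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if len(positions) != self.n_variants or np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing, one per variant")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort quotas must be non-negative")


@dataclass(frozen=True)
class HaplotypePanel:
    """Binary haplotypes (rows) over the variants of an `AncestrySpec`."""

    haplotypes: np.ndarray
    spec: AncestrySpec

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        object.__setattr__(self, "haplotypes", h)
        if h.ndim != 2 or h.shape[1] != self.spec.n_variants:
            raise ValueError("haplotypes must be n_hap x n_variants")
        if h.shape[0] % 2 != 0:
            raise ValueError("n_hap must be even (pairs form diploids)")
        if h.size and h.max() > 1:
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class Cohort:
    """Simulated case/control cohort for one ancestry."""

    genotypes: np.ndarray  # n_ind x n_variants, NaN = missing
    status: np.ndarray  # 0 control / 1 case
    admixture: np.ndarray  # n_ind x 3 proportions
    causal_index: int | None
    true_or: float
    spec: AncestrySpec

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    def to_genotype_matrix(self, id_prefix: str = "snp") -> GenotypeMatrix:
        """Package the cohort's genotypes with VCF-style variant metadata."""
        n_var = self.spec.n_variants
        return GenotypeMatrix(
            genotypes=self.genotypes,
            variant_ids=np.array([f"{id_prefix}_{i + 1}" for i in range(n_var)]),
            positions=self.spec.positions,
            ref=np.full(n_var, "A", dtype=object),
            alt=np.full(n_var, "G", dtype=object),
            sample_ids=np.array(
                [f"{self.spec.name}_ind_{i + 1}" for i in range(self.n_samples)]
            ),
            groups=np.full(self.n_samples, self.spec.name, dtype=object),
        )


@dataclass
class ExpressionMatrix:
    """Samples x genes expression with optional group labels."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be samples x genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("ids must align with the value matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if len(self.groups) != len(self.sample_ids):
                raise ValueError("groups must align with samples")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def simulate_haplotype_panel(
    spec: AncestrySpec, n_hap: int, seed: int
) -> HaplotypePanel:
    """Draw haplotypes from a thresholded latent AR(1) Gaussian.

    Each haplotype is a stationary AR(1) series with lag-1 correlation
    ``spec.ld_rho`` and standard normal marginals; site j carries the
    alternate allele when the latent value exceeds the normal quantile
    Phi^{-1}(1 - alt_freq_j), so per-site frequencies match ``alt_freqs``
    in expectation while adjacent-site allelic correlation grows with
    ``ld_rho``.
    """
    if n_hap < 2 or n_hap % 2 != 0:
        raise ValueError("n_hap must be an even count >= 2")
    rng = np.random.default_rng(seed)
    rho = spec.ld_rho
    m = spec.n_variants
    x = np.empty((n_hap, m))
    innov = rng.standard_normal((n_hap, m))
    x[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        x[:, j] = rho * x[:, j - 1] + scale * innov[:, j]
    thresholds = ndtri(1.0 - spec.alt_freqs)
    haplotypes = (x > thresholds).astype(np.uint8)
    return HaplotypePanel(haplotypes=haplotypes, spec=spec)


def simulate_case_control(
    panel: HaplotypePanel,
    causal_index: int,
    or_per_allele: float,
    base_rate: float = 0.2,
    admixture_effect: np.ndarray | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    missing_rate: float = 0.02,
    seed: int = 0,
    max_draws: int = 5_000_000,
) -> Cohort:
    """Sample a case/control cohort under a logistic disease model.

    Individuals are formed by pairing haplotypes drawn with replacement
    from ``panel``; disease status is Bernoulli with
    ``logit P(case) = logit(base_rate) + ln(OR) * g_causal + a . admixture``
    and sampling continues until both quotas are met.  Missing genotypes
    are masked completely at random at ``missing_rate``.
    """
    spec = panel.spec
    n_cases = spec.n_cases if n_cases is None else n_cases
    n_controls = spec.n_controls if n_controls is None else n_controls
    if not 0 <= causal_index < spec.n_variants:
        raise ValueError("causal_index out of range")
    if or_per_allele <= 0:
        raise ValueError("or_per_allele must be positive")
    if not 0 < base_rate < 1:
        raise ValueError(
            "base_rate must lie strictly in (0, 1); a degenerate rate makes a "
            "case or control quota unattainable"
        )
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    a = np.zeros(3) if admixture_effect is None else np.asarray(admixture_effect, float)
    if a.shape != (3,):
        raise ValueError("admixture_effect must be a 3-vector")

    rng = np.random.default_rng(seed)
    alpha = logit(base_rate)
    beta = np.log(or_per_allele)

    geno_chunks: list[np.ndarray] = []
    admix_chunks: list[np.ndarray] = []
    status_chunks: list[np.ndarray] = []
    got_cases = got_controls = 0
    drawn = 0
    batch = max(1024, 2 * (n_cases + n_controls))
    while got_cases < n_cases or got_controls < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quotas not met after {drawn} draws "
                f"(cases {got_cases}/{n_cases}, controls {got_controls}/{n_controls})"
            )
        idx = rng.integers(0, panel.n_hap, size=(batch, 2))
        g = (
            panel.haplotypes[idx[:, 0]].astype(np.int16)
            + panel.haplotypes[idx[:, 1]]
        ).astype(float)
        admix = rng.dirichlet(np.ones(4), size=batch)[:, :3]
        eta = alpha + beta * g[:, causal_index] + admix @ a
        y = (rng.random(batch) < expit(eta)).astype(np.int8)
        drawn += batch
        need_case = n_cases - got_cases
        need_control = n_controls - got_controls
        case_rows = np.flatnonzero(y == 1)[:need_case]
        control_rows = np.flatnonzero(y == 0)[:need_control]
        keep = np.concatenate([case_rows, control_rows])
        geno_chunks.append(g[keep])
        admix_chunks.append(admix[keep])
        status_chunks.append(y[keep])
        got_cases += len(case_rows)
        got_controls += len(control_rows)

    genotypes = np.concatenate(geno_chunks, axis=0)
    admixture = np.concatenate(admix_chunks, axis=0)
    status = np.concatenate(status_chunks, axis=0).astype(np.int8)
    order = rng.permutation(len(status))
    genotypes, admixture, status = genotypes[order], admixture[order], status[order]
    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes[mask] = np.nan
    return Cohort(
        genotypes=genotypes,
        status=status,
        admixture=admixture,
        causal_index=causal_index,
        true_or=or_per_allele,
        spec=spec,
    )


def simulate_eqtl_expression(
    genotypes: GenotypeMatrix,
    target_gene: str,
    beta: float,
    noise_sd: float,
    n_null_genes: int = 0,
    variant_index: int = 0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Genotype-additive expression for one target gene plus pure-noise genes.

    The target gene is ``beta * g + N(0, noise_sd^2)`` on the variant at
    ``variant_index`` (missing genotypes contribute no genetic term);
    null genes are independent ``N(0, noise_sd^2)`` noise.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not 0 <= variant_index < genotypes.n_variants:
        raise ValueError("variant_index out of range")
    rng = np.random.default_rng(seed)
    g = np.nan_to_num(genotypes.genotypes[:, variant_index], nan=0.0)
    n = genotypes.n_samples
    values = np.empty((n, 1 + n_null_genes))
    values[:, 0] = beta * g + rng.normal(0.0, noise_sd, size=n)
    if n_null_genes:
        values[:, 1:] = rng.normal(0.0, noise_sd, size=(n, n_null_genes))
    gene_ids = np.array(
        [target_gene] + [f"null_gene_{i + 1}" for i in range(n_null_genes)],
        dtype=object,
    )
    return ExpressionMatrix(
        values=values, gene_ids=gene_ids, sample_ids=genotypes.sample_ids
    )


def simulate_ifn_panel(
    n_nc: int,
    n_treated: int,
    gene_means: np.ndarray = (10.0, 8.0, 6.0, 4.0),
    gene_sds: np.ndarray = (2.0, 2.0, 1.0, 1.0),
    treated_shift: np.ndarray = (0.0, 0.0, 0.0, 0.0),
    seed: int = 0,
    genes: tuple[str, ...] = IFN_GENES,
) -> ExpressionMatrix:
    """Negative-control / treated expression panel for the IFN signature genes.

    NC samples are N(gene_means, gene_sds^2) per gene; treated samples are
    shifted by ``treated_shift`` on the same noise law.
    """
    mu = np.asarray(gene_means, dtype=float)
    sd = np.asarray(gene_sds, dtype=float)
    shift = np.asarray(treated_shift, dtype=float)
    k = len(genes)
    if not (len(mu) == len(sd) == len(shift) == k):
        raise ValueError("gene_means, gene_sds, treated_shift must match gene count")
    if np.any(sd <= 0):
        raise ValueError("gene_sds must be positive")
    if n_nc < 2:
        raise ValueError("at least two NC samples are required (SD undefined below)")
    rng = np.random.default_rng(seed)
    nc = rng.normal(mu, sd, size=(n_nc, k))
    treated = rng.normal(mu + shift, sd, size=(n_treated, k))
    values = np.vstack([nc, treated])
    sample_ids = np.array(
        [f"NC_{i + 1}" for i in range(n_nc)]
        + [f"treated_{i + 1}" for i in range(n_treated)],
        dtype=object,
    )
    groups = np.array(["NC"] * n_nc + ["treated"] * n_treated, dtype=object)
    return ExpressionMatrix(
        values=values, gene_ids=np.array(genes, dtype=object),
        sample_ids=sample_ids, groups=groups,
    )


def simulate_t7_bands(
    true_cleaved_fraction: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    scale: float = 100.0,
) -> T7Bands:
    """Gel band intensities with a known cleaved fraction.

    The substrate band gets ``(1 - f) * scale`` and the two cleavage
    products split ``f * scale``; each band is perturbed by multiplicative
    log-normal noise with coefficient of variation ``noise_cv``.
    """
    f = true_cleaved_fraction
    if not 0 <= f <= 1:
        raise ValueError("true_cleaved_fraction must lie in [0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    ideal = np.array([(1.0 - f) * scale, f * scale / 2.0, f * scale / 2.0])
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=3)
    else:
        noise = np.ones(3)
    a, b, c = ideal * noise
    return T7Bands(a=float(a), b=float(b), c=float(c))
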