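"""Additive-model association scans.

Case/control association is a per-variant maximum-likelihood logistic
regression, logit P(case) = alpha + beta * g + gamma . covariates, fitted
by iteratively reweighted least squares (IRLS).  The per-allele log-odds
beta is reported for the alternate allele as coded in the VCF, with a Wald
z and two-sided normal p-value.  Expression scans use ordinary least
squares with a Student-t slope test.  Missing genotypes are handled by
per-variant complete-case analysis; no genomic control is applied.

Separation (the MLE diverging) is detected by the coefficient magnitude
exceeding a bound during IRLS; such fits are flagged unconverged and carry
no p-value, never a silently unstable number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .genotypes import GenotypeMatrix
from .synthgen import ExpressionMatrix

__all__ = [
    "AssocRecord",
    "EqtlRecord",
    "ConditionalStep",
    "ConditionalTrace",
    "fit_logistic",
    "logistic_scan",
    "conditional_stepwise",
    "eqtl_scan",
    "assoc_frame",
    "eqtl_frame",
]

IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8
SEPARATION_BETA_BOUND = 15.0


@dataclass(frozen=True)
class AssocRecord:
    """Per-variant logistic association result (beta per alternate allele)."""

    variant_id: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    converged: bool
    position: int = 0


@dataclass(frozen=True)
class EqtlRecord:
    """Per variant x gene linear-model eQTL result."""

    variant_id: str
    gene_id: str
    slope: float
    se: float
    t: float
    p: float
    n: int
    estimable: bool


class AliasedPredictorError(ValueError):
    """The design matrix is rank deficient (a predictor is aliased)."""


def fit_logistic(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit of a logistic regression; returns (beta, se, converged).

    ``X`` must include any intercept column.  Convergence requires the
    max coefficient update to fall below 1e-8 within 50 iterations with
    all |beta| <= 15; rank-deficient designs raise
    :class:`AliasedPredictorError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise AliasedPredictorError("design matrix is rank deficient")
    beta = np.zeros(k)
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        xtw = X.T * w
        try:
            delta = np.linalg.solve(xtw @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BETA_BOUND:
            return beta, np.full(k, np.nan), False
        if np.max(np.abs(delta)) < IRLS_TOL:
            converged = True
            break
    if not converged:
        return beta, np.full(k, np.nan), False
    mu = expit(X @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, True


def _design(
    g_col: np.ndarray,
    covariates: np.ndarray | None,
    extra: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case design matrix [1, g, covariates, extra] and row mask."""
    cols = [g_col]
    if covariates is not None:
        cols.append(covariates)
    if extra is not None:
        cols.append(extra)
    full = np.column_stack(cols)
    rows = ~np.isnan(full).any(axis=1)
    X = np.column_stack([np.ones(rows.sum()), full[rows]])
    return X, rows


def logistic_scan(
    g: GenotypeMatrix,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    variants: np.ndarray | None = None,
    condition_genotypes: np.ndarray | None = None,
) -> list[AssocRecord]:
    """Per-variant additive logistic scan with optional covariates.

    ``condition_genotypes`` (samples x conditioned variants) are appended
    to the covariates, which is how conditional analyses are run.  Samples
    missing the genotype, any covariate, or any conditioning genotype are
    dropped for that variant.
    """
    status = np.asarray(status, dtype=float)
    if not np.all(np.isin(status[~np.isnan(status)], [0.0, 1.0])):
        raise ValueError("status must be binary 0/1")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != g.n_samples:
            raise ValueError("covariate rows must align with samples")
    idx = np.arange(g.n_variants) if variants is None else np.asarray(variants)
    records: list[AssocRecord] = []
    for j in idx:
        g_col = g.genotypes[:, j]
        X, rows = _design(g_col, covariates, condition_genotypes)
        y = status[rows]
        valid = ~np.isnan(y)
        X, y = X[valid], y[valid]
        n = len(y)
        try:
            beta, se, ok = fit_logistic(X, y)
        except AliasedPredictorError:
            beta, se, ok = np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan), False
        b, s = float(beta[1]), float(se[1])
        if ok and s > 0:
            z = b / s
            p = 2.0 * stats.norm.sf(abs(z))
        else:
            ok = False
            z = np.nan
            p = np.nan
        records.append(
            AssocRecord(
                variant_id=str(g.variant_ids[j]),
                beta=b if ok else np.nan,
                se=s if ok else np.nan,
                z=z,
                p=p,
                n=n,
                converged=ok,
                position=int(g.positions[j]),
            )
        )
    return records


@dataclass
class ConditionalStep:
    """One round of conditioning: the variant added and the resulting scan."""

    conditioned_on: list[str]
    records: list[AssocRecord]
    top_variant: str | None
    top_p: float
    below_stop: list[str]
    residual_window: list[str]
    aliased: list[str] = field(default_factory=list)


@dataclass
class ConditionalTrace:
    steps: list[ConditionalStep]

    @property
    def n_signals(self) -> int:
        """Number of variants that were conditioned on before the scan cleared."""
        return len(self.steps[-1].conditioned_on) if self.steps else 0


def conditional_stepwise(
    g: GenotypeMatrix,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    p_stop: float = 1e-4,
    p_report_hi: float = 1e-2,
    max_steps: int = 20,
) -> ConditionalTrace:
    """Stepwise conditional logistic analysis.

    The scan's top variant (lowest p, ties broken by lowest genomic
    position) is added as a model covariate and the region re-scanned;
    iteration stops when no variant remains below ``p_stop``.  Each step
    records variants still below ``p_stop`` and variants with residual
    evidence in the window ``p_stop < p < p_report_hi``.  Conditioned
    variants (and anything collinear with them) are reported as aliased
    and skipped; missing conditioning genotypes are mean-imputed so the
    complete-case sample does not shrink with every step.
    """
    conditioned: list[int] = []
    steps: list[ConditionalStep] = []
    for _ in range(max_steps):
        if conditioned:
            cond = g.genotypes[:, conditioned].copy()
            col_means = np.nanmean(cond, axis=0)
            nan_rows, nan_cols = np.where(np.isnan(cond))
            cond[nan_rows, nan_cols] = col_means[nan_cols]
        else:
            cond = None
        records = logistic_scan(
            g, status, covariates=covariates, condition_genotypes=cond
        )
        aliased = [
            r.variant_id
            for k, r in enumerate(records)
            if not r.converged and k in conditioned
        ]
        candidates = [
            (r.p, g.positions[k], k, r)
            for k, r in enumerate(records)
            if r.converged and k not in conditioned and not np.isnan(r.p)
        ]
        below = [r.variant_id for _, _, _, r in candidates if r.p < p_stop]
        window = [
            r.variant_id for _, _, _, r in candidates if p_stop < r.p < p_report_hi
        ]
        if candidates:
            top_p, _, top_idx, top_rec = min(candidates, key=lambda t: (t[0], t[1]))
            top_id = top_rec.variant_id
        else:
            top_p, top_idx, top_id = np.nan, None, None
        steps.append(
            ConditionalStep(
                conditioned_on=[str(g.variant_ids[k]) for k in conditioned],
                records=records,
                top_variant=top_id,
                top_p=float(top_p),
                below_stop=below,
                residual_window=window,
                aliased=aliased,
            )
        )
        if top_idx is None or not (top_p < p_stop):
            break
        conditioned.append(top_idx)
    return ConditionalTrace(steps=steps)


def _ols_slope(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit; returns (slope, se, t, p) for column 1 of X."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k or n <= k:
        return np.nan, np.nan, np.nan, np.nan
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    slope = float(beta[1])
    if se == 0:
        # noiseless fit: slope exact, p-value degenerate at 0
        return slope, 0.0, np.inf, 0.0
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - k)
    return slope, se, float(t), float(p)


def eqtl_scan(
    g: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    variants: np.ndarray | None = None,
    condition_on: list[str] | None = None,
    p_report: float = 1e-4,
) -> list[EqtlRecord]:
    """Additive linear-model eQTL scan: expression ~ genotype (+ conditioning).

    Samples are matched by id between the genotype matrix and the
    expression matrix; each variant x gene pair is fitted by OLS on the
    complete cases, with the genotypes of ``condition_on`` variants as
    additional covariates.  ``p_report`` is the conventional reporting
    threshold and is attached to frames via :func:`eqtl_frame`, not used
    to drop records here.  Constant-genotype fits are flagged
    non-estimable with no slope.
    """
    expr_ids = list(expr.sample_ids)
    geno_ids = list(g.sample_ids)
    common = [s for s in geno_ids if s in set(expr_ids)]
    if not common:
        raise ValueError("no shared sample ids between genotypes and expression")
    g_rows = np.array([geno_ids.index(s) for s in common])
    e_rows = np.array([expr_ids.index(s) for s in common])
    geno = g.genotypes[g_rows]
    values = expr.values[e_rows]

    cond = None
    if condition_on:
        cond_idx = [g.variant_index(v) for v in condition_on]
        cond = geno[:, cond_idx]

    gene_list = list(expr.gene_ids) if genes is None else list(genes)
    gene_cols = {str(gid): i for i, gid in enumerate(expr.gene_ids)}
    var_idx = np.arange(g.n_variants) if variants is None else np.asarray(variants)
    records: list[EqtlRecord] = []
    for gene in gene_list:
        if gene not in gene_cols:
            raise KeyError(f"gene not in expression matrix: {gene}")
        y_full = values[:, gene_cols[gene]]
        for j in var_idx:
            g_col = geno[:, j]
            cols = [g_col] if cond is None else [g_col, cond]
            full = np.column_stack(cols)
            rows = ~np.isnan(full).any(axis=1) & ~np.isnan(y_full)
            X = np.column_stack([np.ones(rows.sum()), full[rows]])
            y = y_full[rows]
            n = len(y)
            vid = str(g.variant_ids[j])
            if n < X.shape[1] + 1 or np.ptp(g_col[rows]) == 0:
                records.append(
                    EqtlRecord(vid, gene, np.nan, np.nan, np.nan, np.nan, n, False)
                )
                continue
            slope, se, t, p = _ols_slope(X, y)
            records.append(
                EqtlRecord(
                    vid, gene, slope, se, t, p, n, estimable=not np.isnan(slope)
                )
            )
    return records


# ---------------------------------------------------------------------------
# Tabular views
# ---------------------------------------------------------------------------


def assoc_frame(g: GenotypeMatrix, records: list[AssocRecord]) -> pd.DataFrame:
    """Standard association output table (CHR POS ID A1 A2 N BETA SE Z P CONVERGED)."""
    meta = {str(v): k for k, v in enumerate(g.variant_ids)}
    rows = []
    for r in records:
        k = meta[r.variant_id]
        rows.append(
            {
                "CHR": g.chrom[k],
                "POS": g.positions[k],
                "ID": r.variant_id,
                "A1": g.alt[k],
                "A2": g.ref[k],
                "N": r.n,
                "BETA": r.beta,
                "SE": r.se,
                "Z": r.z,
                "P": r.p,
                "CONVERGED": r.converged,
            }
        )
    return pd.DataFrame(rows)


def eqtl_frame(records: list[EqtlRecord], p_report: float | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "ID": r.variant_id,
                "GENE": r.gene_id,
                "N": r.n,
                "SLOPE": r.slope,
                "SE": r.se,
                "T": r.t,
                "P": r.p,
                "ESTIMABLE": r.estimable,
            }
            for r in records
        ]
    )
    if p_report is not None and len(df):
        df = df[df["P"] < p_report].reset_index(drop=True)
    return df
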