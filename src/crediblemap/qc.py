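"""Variant- and sample-level quality control for case/control genotype data.

Filter order follows the dependency between the rules: variant filters
(per-group MAF, variant call rate, imputation r²) run first, then the
sample call-rate filter is computed on surviving variants, then relatedness
pruning (π̂) runs on the cleaned matrix.

Note on the sample call-rate rule: the conventional direction — exclude
samples whose call rate falls *below* the threshold — is implemented.
Descriptions of this rule sometimes appear with the inequality inverted,
which would discard the best-genotyped samples; the threshold and direction
here are explicit and configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "QcReport",
    "PihatResult",
    "filter_variants",
    "filter_samples",
    "filter_info",
    "estimate_pihat",
    "pairwise_pihat",
    "remove_related",
    "run_qc",
]

MIN_PIHAT_OVERLAP = 50


@dataclass
class QcReport:
    """What a filter removed and why; partitions the input exactly."""

    removed_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["item", "reason", "value", "threshold"]
        )
    )
    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["item", "reason", "value", "threshold"]
        )
    )
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        v = self.removed_variants.assign(type="variant")
        s = self.removed_samples.assign(type="sample")
        frames = [f for f in (v, s) if len(f)]
        if not frames:
            return pd.DataFrame(columns=["item", "type", "reason", "value", "threshold"])
        return pd.concat(frames, ignore_index=True)[
            ["item", "type", "reason", "value", "threshold"]
        ]


def filter_variants(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    per_group: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop variants with MAF < ``maf_min`` in any group or call rate < ``call_rate_min``.

    Both filters are strict ``<``: a variant sitting exactly at a threshold
    is kept.  With ``per_group`` the MAF rule is applied within every
    sample group and failing any one group removes the variant; a variant
    with no observed calls in some group has undefined group MAF and is
    removed under the MAF reason.
    """
    if per_group:
        if g.groups is None:
            raise ValueError("per-group MAF filtering requires sample group labels")
        group_rows = {
            name: np.flatnonzero(g.groups == name) for name in pd.unique(g.groups)
        }
        for name, rows in group_rows.items():
            if len(rows) == 0:
                raise ValueError(f"empty sample group: {name}")
        group_mafs = {name: g.maf(rows) for name, rows in group_rows.items()}
    else:
        group_mafs = {"all": g.maf()}

    call_rate = g.variant_call_rate()
    removed: dict[int, tuple[str, float, float]] = {}
    for name, maf in group_mafs.items():
        fails = np.isnan(maf) | (maf < maf_min)
        for j in np.flatnonzero(fails):
            if j not in removed:
                removed[j] = ("maf", float(maf[j]), maf_min)
    for j in np.flatnonzero(call_rate < call_rate_min):
        if j not in removed:
            removed[j] = ("call_rate", float(call_rate[j]), call_rate_min)

    keep = np.array([j for j in range(g.n_variants) if j not in removed], dtype=int)
    report = QcReport(
        removed_variants=pd.DataFrame(
            [
                (g.variant_ids[j], reason, value, thr)
                for j, (reason, value, thr) in sorted(removed.items())
            ],
            columns=["item", "reason", "value", "threshold"],
        ),
        thresholds={"maf_min": maf_min, "call_rate_min": call_rate_min},
    )
    return g.take_variants(keep), report


def filter_samples(
    g: GenotypeMatrix, sample_call_rate_min: float = 0.95
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose call rate over the current variants is < threshold."""
    rate = g.sample_call_rate()
    fails = np.flatnonzero(rate < sample_call_rate_min)
    if len(fails) == g.n_samples:
        raise ValueError("sample call-rate filter would remove every sample")
    keep = np.flatnonzero(rate >= sample_call_rate_min)
    report = QcReport(
        removed_samples=pd.DataFrame(
            [
                (g.sample_ids[i], "call_rate", float(rate[i]), sample_call_rate_min)
                for i in fails
            ],
            columns=["item", "reason", "value", "threshold"],
        ),
        thresholds={"sample_call_rate_min": sample_call_rate_min},
    )
    return g.take_samples(keep), report


def filter_info(
    g: GenotypeMatrix, r2_min: float = 0.8
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop imputed variants with imputation r² < ``r2_min`` (strict).

    Directly genotyped variants (r² of NaN) are untouched; a matrix
    without r² scores passes through unchanged.
    """
    if g.info_r2 is None:
        return g, QcReport(thresholds={"r2_min": r2_min})
    r2 = g.info_r2
    fails = np.flatnonzero(~np.isnan(r2) & (r2 < r2_min))
    keep = np.array([j for j in range(g.n_variants) if j not in set(fails)], dtype=int)
    report = QcReport(
        removed_variants=pd.DataFrame(
            [(g.variant_ids[j], "info", float(r2[j]), r2_min) for j in fails],
            columns=["item", "reason", "value", "threshold"],
        ),
        thresholds={"r2_min": r2_min},
    )
    return g.take_variants(keep), report


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PihatResult:
    pihat: float
    n_overlap: int
    reliable: bool


def _ibd_expectations(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-variant IBS-class probabilities conditional on IBD state.

    Standard method-of-moments quantities for unrelated-pair (IBD 0),
    one-allele-shared (IBD 1) and duplicate (IBD 2) states at a biallelic
    site with alternate frequency p under Hardy-Weinberg proportions.
    """
    q = 1.0 - p
    e_ibs0_ibd0 = 2.0 * p**2 * q**2
    e_ibs1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e_ibs2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e_ibs1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e_ibs2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2
    return e_ibs0_ibd0, e_ibs1_ibd0, e_ibs2_ibd0, e_ibs1_ibd1, e_ibs2_ibd1


def _project_ibd(p0, p1, p2):
    """Project raw moment estimates of the IBD-state proportions onto the simplex.

    A pair whose raw P(IBD=0) exceeds 1 is called unrelated outright (the
    standard GWAS-toolkit boundary treatment); negative components are
    floored at 0 and the triple renormalized, and π̂ = P1/2 + P2.
    """
    p0, p1, p2 = (np.asarray(x, dtype=float) for x in (p0, p1, p2))
    unrelated = p0 > 1
    p1 = np.where(unrelated, 0.0, p1)
    p2 = np.where(unrelated, 0.0, p2)
    p0 = np.where(unrelated, 1.0, p0)
    p0, p1, p2 = np.maximum(p0, 0), np.maximum(p1, 0), np.maximum(p2, 0)
    total = p0 + p1 + p2
    total = np.where(total > 0, total, 1.0)
    return np.clip((p1 / total) / 2.0 + (p2 / total), 0.0, 1.0)


def pairwise_pihat(g: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments π̂ for all sample pairs (vectorized over pairs).

    Uses hard-call indicators; dosages are rounded to the nearest hard
    call for IBS counting.  Entries on the diagonal are 1 by construction.
    """
    geno = g.genotypes
    freqs = g.alt_freq()
    valid_var = ~np.isnan(freqs) & (freqs > 0) & (freqs < 1)
    geno = geno[:, valid_var]
    p = freqs[valid_var]

    hard = np.round(geno)
    called = ~np.isnan(hard)
    g0 = (called & (hard == 0)).astype(float)
    g1 = (called & (hard == 1)).astype(float)
    g2 = (called & (hard == 2)).astype(float)
    c = called.astype(float)

    # pairwise IBS class counts via matrix products over variants
    ibs2 = g0 @ g0.T + g1 @ g1.T + g2 @ g2.T
    ibs0 = g0 @ g2.T + g2 @ g0.T
    overlap = c @ c.T
    ibs1 = overlap - ibs2 - ibs0

    e00, e10, e20, e11, e21 = _ibd_expectations(p)
    # expected counts restricted to each pair's overlapping variants
    s00 = c * e00 @ c.T
    s10 = c * e10 @ c.T
    s20 = c * e20 @ c.T
    s11 = c * e11 @ c.T
    s21 = c * e21 @ c.T

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.nan_to_num(ibs0 / s00)
        p1 = np.nan_to_num((ibs1 - p0 * s10) / s11)
        p2 = np.nan_to_num((ibs2 - p0 * s20 - p1 * s21) / overlap)
    return _project_ibd(p0, p1, p2)


def estimate_pihat(g: GenotypeMatrix, i: int | str, j: int | str) -> PihatResult:
    """π̂ = P(IBD=1)/2 + P(IBD=2) for one sample pair.

    Estimated by method of moments from observed IBS0/IBS1/IBS2 counts and
    study allele frequencies, clipped to [0, 1].  Pairs with fewer than
    50 overlapping non-missing variants are flagged unreliable.
    """
    if isinstance(i, str):
        i = int(np.flatnonzero(g.sample_ids == i)[0])
    if isinstance(j, str):
        j = int(np.flatnonzero(g.sample_ids == j)[0])
    overlap = int(
        np.sum(~np.isnan(g.genotypes[i]) & ~np.isnan(g.genotypes[j]))
    )
    # frequencies must come from the full study, not the pair
    full = pairwise_pihat_for_pair(g, i, j)
    return PihatResult(pihat=full, n_overlap=overlap, reliable=overlap >= MIN_PIHAT_OVERLAP)


def pairwise_pihat_for_pair(g: GenotypeMatrix, i: int, j: int) -> float:
    geno = g.genotypes
    freqs = g.alt_freq()
    valid = (
        ~np.isnan(freqs)
        & (freqs > 0)
        & (freqs < 1)
        & ~np.isnan(geno[i])
        & ~np.isnan(geno[j])
    )
    p = freqs[valid]
    a = np.round(geno[i, valid])
    b = np.round(geno[j, valid])
    ibs = 2.0 - np.abs(a - b)
    n = len(p)
    if n == 0:
        return 0.0
    n_ibs0 = float(np.sum(ibs == 0))
    n_ibs1 = float(np.sum(ibs == 1))
    n_ibs2 = float(np.sum(ibs == 2))
    e00, e10, e20, e11, e21 = (arr.sum() for arr in _ibd_expectations(p))
    p0 = n_ibs0 / e00 if e00 > 0 else 0.0
    p1 = (n_ibs1 - p0 * e10) / e11 if e11 > 0 else 0.0
    p2 = (n_ibs2 - p0 * e20 - p1 * e21) / n
    return float(np.asarray(_project_ibd(p0, p1, p2)))


def remove_related(
    g: GenotypeMatrix, pihat_max: float = 0.4
) -> tuple[GenotypeMatrix, QcReport]:
    """Greedy pruning of duplicate / first-degree pairs (π̂ > ``pihat_max``).

    Pairs are visited in descending π̂ order; from each still-intact pair
    the member with the lower call rate is removed (ties: the later
    sample), so the best-genotyped copy of each duplicate cluster survives.
    """
    n = g.n_samples
    pihat = pairwise_pihat(g)
    call_rate = g.sample_call_rate()
    pairs = [
        (pihat[i, j], i, j)
        for i, j in itertools.combinations(range(n), 2)
        if pihat[i, j] > pihat_max
    ]
    pairs.sort(key=lambda t: -t[0])
    removed: dict[int, float] = {}
    for value, i, j in pairs:
        if i in removed or j in removed:
            continue
        # drop the lower-call-rate member; on exact ties, the second sample
        drop = j if call_rate[j] <= call_rate[i] else i
        removed[drop] = value
    keep = np.array([i for i in range(n) if i not in removed], dtype=int)
    report = QcReport(
        removed_samples=pd.DataFrame(
            [
                (g.sample_ids[i], "relatedness", float(v), pihat_max)
                for i, v in sorted(removed.items())
            ],
            columns=["item", "reason", "value", "threshold"],
        ),
        thresholds={"pihat_max": pihat_max},
    )
    return g.take_samples(keep), report


def run_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    sample_call_rate_min: float = 0.95,
    pihat_max: float = 0.4,
    r2_min: float = 0.8,
    per_group: bool = True,
    relatedness: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC chain: info -> variant filters -> sample call rate -> relatedness."""
    g1, rep_info = filter_info(g, r2_min=r2_min)
    g2, rep_var = filter_variants(
        g1, maf_min=maf_min, call_rate_min=call_rate_min, per_group=per_group
    )
    g3, rep_samp = filter_samples(g2, sample_call_rate_min=sample_call_rate_min)
    if relatedness:
        g4, rep_rel = remove_related(g3, pihat_max=pihat_max)
    else:
        g4, rep_rel = g3, QcReport()
    def _cat(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
        frames = [f for f in (a, b) if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else a.iloc[0:0]

    report = QcReport(
        removed_variants=_cat(rep_info.removed_variants, rep_var.removed_variants),
        removed_samples=_cat(rep_samp.removed_samples, rep_rel.removed_samples),
        thresholds={
            "maf_min": maf_min,
            "call_rate_min": call_rate_min,
            "sample_call_rate_min": sample_call_rate_min,
            "pihat_max": pihat_max,
            "r2_min": r2_min,
        },
    )
    return g4, report
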