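"""Bench-assay statistics: IFN signature score, T7 endonuclease I editing
efficiency, qPCR fold enrichment, and allelic read imbalance.

The IFN score standardizes each interferon-inducible signature gene against
the negative-control group (subtract NC mean, divide by NC SD) and sums the
standardized values per sample, so the NC group mean score is 0 by
construction.  T7EI editing efficiency converts the cleaved band fraction
f = (b + c) / (a + b + c) into the fraction of edited alleles via
100 * (1 - sqrt(1 - f)), where a is the uncut substrate band and b, c the
cleavage products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IFN_GENES",
    "IfnPanel",
    "T7Bands",
    "EditingResult",
    "AllelicCounts",
    "ifn_score",
    "t7_efficiency",
    "fold_enrichment",
    "allelic_imbalance",
]

#: Default interferon-inducible signature genes.
IFN_GENES = ("IFI27", "IFIT3", "OAS1", "LY6E")

#: Editing efficiency (percent) above which a T7EI sample is usable.
T7_USABLE_MIN_PCT = 40.0


@dataclass(frozen=True)
class T7Bands:
    """Band intensities from a T7EI cleavage gel: substrate ``a``, products ``b``, ``c``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("band intensities must be non-negative")
        if self.a + self.b + self.c <= 0:
            raise ValueError("total band intensity must be positive")

    @property
    def cleaved_fraction(self) -> float:
        return (self.b + self.c) / (self.a + self.b + self.c)


@dataclass(frozen=True)
class EditingResult:
    bands: T7Bands
    cleaved_fraction: float
    efficiency_pct: float
    usable: bool


@dataclass(frozen=True)
class AllelicCounts:
    """Reference/alternate read counts at a heterozygous site."""

    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_reads + self.alt_reads < 1:
            raise ValueError("at least one read is required")


@dataclass
class IfnPanel:
    """IFN-score result: per-gene NC statistics and per-sample scores."""

    expression: pd.DataFrame
    nc_mask: np.ndarray
    genes: tuple[str, ...]
    nc_mean: pd.Series = field(init=False)
    nc_sd: pd.Series = field(init=False)
    scores: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.nc_mask = np.asarray(self.nc_mask, dtype=bool)
        if len(self.nc_mask) != len(self.expression):
            raise ValueError("nc_mask must align with expression rows")


def ifn_score(
    expression: pd.DataFrame,
    nc_mask: np.ndarray,
    genes: tuple[str, ...] = IFN_GENES,
    ddof: int = 1,
) -> IfnPanel:
    """Per-sample IFN score: sum over signature genes of NC-standardized expression.

    Parameters
    ----------
    expression
        Samples x genes table of relative expression; must contain every
        gene in ``genes``.
    nc_mask
        Boolean flag per sample, True for negative-control samples.  At
        least two NC samples are required so the NC SD is defined.
    ddof
        SD denominator convention; 1 (sample SD) by default.
    """
    panel = IfnPanel(expression=expression, nc_mask=nc_mask, genes=tuple(genes))
    missing = [g for g in panel.genes if g not in expression.columns]
    if missing:
        raise ValueError(f"expression table lacks signature genes: {missing}")
    if panel.nc_mask.sum() < 2:
        raise ValueError("at least two negative-control samples are required")
    sub = expression.loc[:, list(panel.genes)].astype(float)
    nc = sub.loc[panel.nc_mask]
    mu = nc.mean(axis=0)
    sd = nc.std(axis=0, ddof=ddof)
    bad = sd[sd <= 0]
    if len(bad):
        raise ValueError(f"zero negative-control SD for gene(s): {list(bad.index)}")
    standardized = (sub - mu) / sd
    panel.nc_mean = mu
    panel.nc_sd = sd
    panel.scores = standardized.sum(axis=1)
    return panel


def t7_efficiency(bands: T7Bands) -> EditingResult:
    """Editing efficiency from T7EI band intensities.

    efficiency% = 100 * (1 - sqrt(1 - f)) with cleaved fraction
    f = (b + c)/(a + b + c).  Samples above 40% are flagged usable.
    """
    f = bands.cleaved_fraction
    eff = 100.0 * (1.0 - np.sqrt(1.0 - f))
    return EditingResult(
        bands=bands,
        cleaved_fraction=f,
        efficiency_pct=float(eff),
        usable=bool(eff > T7_USABLE_MIN_PCT),
    )


def fold_enrichment(
    target_signal: float,
    control_signal: float,
    mode: str = "linear",
    efficiency: float = 2.0,
) -> float:
    """qPCR fold enrichment of a target sample over its control.

    ``linear`` mode divides raw signals (ChIP over IgG, FAIRE over input);
    ``ct`` mode treats inputs as quantification cycles and returns
    ``efficiency ** (Ct_control - Ct_target)``.
    """
    if mode == "linear":
        if control_signal <= 0:
            raise ValueError("control signal must be positive in linear mode")
        return float(target_signal / control_signal)
    if mode == "ct":
        if not (np.isfinite(target_signal) and np.isfinite(control_signal)):
            raise ValueError("Ct values must be finite")
        return float(efficiency ** (control_signal - target_signal))
    raise ValueError(f"unknown mode: {mode!r}")


def allelic_imbalance(counts: AllelicCounts) -> float:
    """Two-sided exact binomial p-value against a balanced 1:1 null.

    Two-sidedness is the minimum-likelihood definition: the p-value sums
    the probabilities of all outcomes no more likely than the observed one
    (scipy's default for `binomtest`).
    """
    n = counts.ref_reads + counts.alt_reads
    return float(stats.binomtest(counts.ref_reads, n, 0.5).pvalue)
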