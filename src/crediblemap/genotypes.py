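"""Additive genotype container shared by the QC, association and fine-mapping stages.

Genotypes are stored as a dense float matrix of alternate-allele counts
(0/1/2 for hard calls, fractional values in [0, 2] for dosages) with NaN
marking missing calls.  Variant coordinates are 1-based, as in VCF, and the
effect allele throughout the package is the alternate allele as written in
the ALT column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive genotypes with variant/sample metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` float array; alternate-allele counts,
        NaN = missing.
    variant_ids, positions, ref, alt
        Per-variant metadata; positions are 1-based.
    sample_ids
        Unique per-sample identifiers.
    chrom
        Per-variant chromosome labels (a scalar broadcastable string is
        accepted and expanded).
    groups
        Optional per-sample cohort label (ancestral group); required by
        per-group QC filters.
    info_r2
        Optional per-variant imputation quality r²; NaN marks directly
        genotyped variants, which imputation filters never touch.
    """

    genotypes: np.ndarray
    variant_ids: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    sample_ids: np.ndarray
    chrom: np.ndarray | str = "1"
    groups: np.ndarray | None = None
    info_r2: np.ndarray | None = None
    dosage: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x variants array")
        n_samples, n_variants = self.genotypes.shape
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if isinstance(self.chrom, str):
            self.chrom = np.full(n_variants, self.chrom, dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
        for name, arr, n in (
            ("variant_ids", self.variant_ids, n_variants),
            ("positions", self.positions, n_variants),
            ("ref", self.ref, n_variants),
            ("alt", self.alt, n_variants),
            ("chrom", self.chrom, n_variants),
            ("sample_ids", self.sample_ids, n_samples),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if len(set(self.variant_ids)) != n_variants:
            raise ValueError("variant ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample ids must be unique")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
            if len(self.groups) != n_samples:
                raise ValueError("groups must align with samples")
        if self.info_r2 is not None:
            self.info_r2 = np.asarray(self.info_r2, dtype=float)
            if len(self.info_r2) != n_variants:
                raise ValueError("info_r2 must align with variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.genotypes, initial=0.0) < 0 or np.nanmax(
                self.genotypes, initial=0.0
            ) > 2:
                raise ValueError("genotype values must lie in [0, 2]")

    # ---- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    # ---- summaries used by QC and association ---------------------------
    def variant_call_rate(self) -> np.ndarray:
        """Fraction of samples with a non-missing call, per variant."""
        return 1.0 - np.isnan(self.genotypes).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of variants with a non-missing call, per sample."""
        return 1.0 - np.isnan(self.genotypes).mean(axis=1)

    def alt_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per variant (mean dosage / 2).

        Variants with no observed calls in the selection yield NaN.
        """
        g = self.genotypes if rows is None else self.genotypes[rows]
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Minor-allele frequency (folded alt frequency)."""
        f = self.alt_freq(rows)
        return np.minimum(f, 1.0 - f)

    # ---- subsetting ------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            variant_ids=self.variant_ids[index],
            positions=self.positions[index],
            ref=self.ref[index],
            alt=self.alt[index],
            chrom=self.chrom[index],
            info_r2=None if self.info_r2 is None else self.info_r2[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            genotypes=self.genotypes[index, :],
            sample_ids=self.sample_ids[index],
            groups=None if self.groups is None else self.groups[index],
        )

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variant_ids == variant_id)
        if len(hits) == 0:
            raise KeyError(f"unknown variant id: {variant_id}")
        return int(hits[0])
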