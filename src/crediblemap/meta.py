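"""Sample-size-weighted Z-score (METAL SAMPLESIZE scheme) meta-analysis.

Each study contributes a signed z-score recovered from its p-value,
z_i = Phi^{-1}(1 - p_i / 2) * sign(effect after allele alignment), and the
combined statistic is

    Z = sum_i w_i z_i / sqrt(sum_i w_i^2),   w_i = sqrt(N_i),

with a two-sided normal p-value.  Effect direction comes from the beta
sign when present, else an explicit direction column; p-only input with no
direction is rejected, since a signed scheme is meaningless without it.
Study alleles are aligned to the first study's orientation, resolving
swapped ref/alt (sign flip) and strand flips (complement); palindromic
A/T and C/G variants are excluded by default because strand cannot be
resolved without allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri_exp
from scipy.stats import norm

__all__ = ["MetaRecord", "align_alleles", "weighted_z_meta", "meta_frame"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class MetaRecord:
    variant_id: str
    z: float
    p: float
    n_total: float
    n_studies: int
    directions: str
    study_z: tuple[float, ...] = field(default=())


def align_alleles(
    a1: str, a2: str, ref_a1: str, ref_a2: str
) -> tuple[float, str]:
    """Alignment sign of a study's (effect, other) alleles to a reference pair.

    Returns ``(sign, status)`` where sign multiplies the study's effect
    direction; status is one of ``match``, ``swap``, ``strand``,
    ``strand_swap``, ``ambiguous`` (palindromic pair) or
    ``irreconcilable``.
    """
    a1, a2, ref_a1, ref_a2 = (x.upper() for x in (a1, a2, ref_a1, ref_a2))
    for allele in (a1, a2, ref_a1, ref_a2):
        if allele not in _COMPLEMENT:
            return 0.0, "irreconcilable"
    if frozenset((a1, a2)) in _PALINDROMIC:
        return 0.0, "ambiguous"
    if (a1, a2) == (ref_a1, ref_a2):
        return 1.0, "match"
    if (a1, a2) == (ref_a2, ref_a1):
        return -1.0, "swap"
    c1, c2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
    if (c1, c2) == (ref_a1, ref_a2):
        return 1.0, "strand"
    if (c1, c2) == (ref_a2, ref_a1):
        return -1.0, "strand_swap"
    return 0.0, "irreconcilable"


def _study_sign(row: pd.Series) -> float:
    if "BETA" in row.index and pd.notna(row.get("BETA")):
        return 1.0 if row["BETA"] >= 0 else -1.0
    if "DIR" in row.index and pd.notna(row.get("DIR")):
        d = str(row["DIR"])
        if d in ("+", "1", "1.0"):
            return 1.0
        if d in ("-", "-1", "-1.0"):
            return -1.0
        raise ValueError(f"unparseable effect direction: {d!r}")
    raise ValueError(
        "signed meta-analysis needs an effect direction (BETA or DIR column)"
    )


def weighted_z_meta(
    studies: list[pd.DataFrame],
    keep_ambiguous: bool = False,
) -> tuple[list[MetaRecord], pd.DataFrame]:
    """Combine per-study summary statistics into weighted-Z meta records.

    Each study table needs columns ID, A1 (effect allele), A2, P, N and
    BETA or DIR.  Variants are keyed by ID; the first study in which a
    variant appears fixes the reference allele orientation.  Returns the
    records plus a log of skipped (variant, study, reason) rows.
    """
    if not studies:
        raise ValueError("at least one study is required")
    per_variant: dict[str, list[tuple[float, float, str]]] = {}
    reference: dict[str, tuple[str, str]] = {}
    skipped: list[tuple[str, int, str]] = []

    for s_idx, df in enumerate(studies):
        required = {"ID", "A1", "A2", "P", "N"}
        if not required <= set(df.columns):
            raise ValueError(f"study {s_idx} lacks columns {required - set(df.columns)}")
        for _, row in df.iterrows():
            vid = str(row["ID"])
            sign = _study_sign(row)
            if vid not in reference:
                align, status = align_alleles(
                    row["A1"], row["A2"], row["A1"], row["A2"]
                )
                if status == "ambiguous" and not keep_ambiguous:
                    skipped.append((vid, s_idx, "ambiguous"))
                    continue
                reference[vid] = (str(row["A1"]).upper(), str(row["A2"]).upper())
                align = 1.0
            else:
                ref_a1, ref_a2 = reference[vid]
                align, status = align_alleles(row["A1"], row["A2"], ref_a1, ref_a2)
                if status == "irreconcilable":
                    skipped.append((vid, s_idx, "irreconcilable"))
                    continue
                if status == "ambiguous":
                    if not keep_ambiguous:
                        skipped.append((vid, s_idx, "ambiguous"))
                        continue
                    align = 1.0 if (row["A1"].upper(), row["A2"].upper()) == (
                        ref_a1,
                        ref_a2,
                    ) else -1.0
            p = float(row["P"])
            if not 0 < p <= 1:
                skipped.append((vid, s_idx, "invalid_p"))
                continue
            z = -ndtri_exp(np.log(p) - np.log(2.0)) * sign * align
            per_variant.setdefault(vid, []).append((z, float(row["N"]), "+" if z >= 0 else "-"))

    records: list[MetaRecord] = []
    for vid, entries in per_variant.items():
        z_arr = np.array([e[0] for e in entries])
        n_arr = np.array([e[1] for e in entries])
        w = np.sqrt(n_arr)
        z_comb = float(np.sum(w * z_arr) / np.sqrt(np.sum(w**2)))
        p_comb = float(2.0 * norm.sf(abs(z_comb)))
        records.append(
            MetaRecord(
                variant_id=vid,
                z=z_comb,
                p=p_comb,
                n_total=float(n_arr.sum()),
                n_studies=len(entries),
                directions="".join(e[2] for e in entries),
                study_z=tuple(float(z) for z in z_arr),
            )
        )
    log = pd.DataFrame(skipped, columns=["ID", "study", "reason"])
    return records, log


def meta_frame(records: list[MetaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ID": r.variant_id,
                "Z": r.z,
                "P": r.p,
                "N_TOTAL": r.n_total,
                "N_STUDIES": r.n_studies,
                "DIRECTIONS": r.directions,
            }
            for r in records
        ]
    )
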