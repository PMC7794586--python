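"""Approximate Bayes factor fine-mapping under a single-causal-variant model.

For each variant the evidence for association is summarized by the
Wakefield approximate Bayes factor comparing the alternative (log-odds
effect b ~ N(0, W)) to the null (b = 0), computed from the effect estimate
and its standard error:

    log BF = 0.5 * log(V / (V + W)) + z^2 * W / (2 * (V + W)),

with V = se^2 and z = beta / se.  Under the assumption that exactly one
variant in the region is causal, the posterior probability of variant i is
its Bayes factor divided by the regional sum, PP_i = BF_i / sum_j BF_j,
and the 95% credible set is the smallest set of variants, taken in
descending PP order, whose PPs sum to at least 0.95.

When only p-values are available (summary-statistic meta-analysis), z is
recovered from the p-value (in log space, so p far below the double
underflow limit of the quantile at 1 - p/2 is still handled) and the
sampling variance is approximated from the sample size and allele
frequency as V = 1 / (2 * n * maf * (1 - maf)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtri_exp

__all__ = [
    "FineMapRecord",
    "CredibleSet",
    "abf_from_summary",
    "abf_from_pvalue",
    "posterior_probs",
    "credible_set",
    "shared_credible_variants",
    "finemap_region",
]

DEFAULT_PRIOR_W = 0.04  # prior SD 0.2 on the log-odds scale
DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class FineMapRecord:
    variant_id: str
    log_bf: float
    pp: float
    prior_w: float
    v: float


@dataclass(frozen=True)
class CredibleSet:
    """Minimal descending-PP credible set at the given level."""

    level: float
    members: tuple[str, ...]
    member_pps: tuple[float, ...]
    cum_pp: float

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.members

    def __len__(self) -> int:
        return len(self.members)


def _validate_w_v(prior_w: float, v: np.ndarray) -> None:
    if prior_w < 0:
        raise ValueError("prior_w must be non-negative")
    if np.any(np.asarray(v) <= 0):
        raise ValueError("sampling variance must be positive")


def abf_from_summary(
    beta: float | np.ndarray, se: float | np.ndarray, prior_w: float = DEFAULT_PRIOR_W
) -> np.ndarray | float:
    """Natural-log Wakefield Bayes factor (alternative vs null) from beta/se."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    v = se**2
    _validate_w_v(prior_w, v)
    z2 = (beta / se) ** 2
    log_bf = 0.5 * np.log(v / (v + prior_w)) + z2 * prior_w / (2.0 * (v + prior_w))
    return float(log_bf) if log_bf.ndim == 0 else log_bf


def abf_from_pvalue(
    p: float | np.ndarray,
    n: float | np.ndarray,
    maf: float | np.ndarray,
    prior_w: float = DEFAULT_PRIOR_W,
    sign: float | np.ndarray = 1.0,
    log_p: float | np.ndarray | None = None,
) -> np.ndarray | float:
    """Log Wakefield Bayes factor recovered from a p-value.

    ``z = Phi^{-1}(1 - p/2) * sign`` is evaluated from log(p) so extreme
    p-values never produce an infinite z; the effect-size sign only
    matters downstream for allele-aligned reporting, not for the BF
    itself.  ``log_p`` may be given instead of ``p`` for values below the
    float underflow limit.
    """
    if log_p is None:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p must lie in (0, 1]")
        log_p = np.log(p)
    log_p = np.asarray(log_p, dtype=float)
    n = np.asarray(n, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("maf must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("n must be positive")
    # z = -Phi^{-1}(p/2), evaluated from log(p/2) to survive underflow
    z = -ndtri_exp(log_p - np.log(2.0)) * np.sign(np.asarray(sign, dtype=float))
    v = 1.0 / (2.0 * n * maf * (1.0 - maf))
    _validate_w_v(prior_w, v)
    log_bf = 0.5 * np.log(v / (v + prior_w)) + z**2 * prior_w / (2.0 * (v + prior_w))
    return float(log_bf) if log_bf.ndim == 0 else log_bf


def posterior_probs(log_bfs: np.ndarray) -> np.ndarray:
    """PP_i = BF_i / sum_j BF_j, computed with log-sum-exp for stability."""
    log_bfs = np.asarray(log_bfs, dtype=float)
    if log_bfs.size == 0:
        raise ValueError("region must contain at least one variant")
    return np.exp(log_bfs - logsumexp(log_bfs))


def credible_set(
    pps: np.ndarray,
    level: float = DEFAULT_LEVEL,
    ids: np.ndarray | None = None,
    include_ties: bool = False,
) -> CredibleSet:
    """Smallest set of variants whose PPs, in descending order, sum to >= level.

    Ties in PP are broken by input order, so the set is minimal by
    construction; with ``include_ties`` every variant tied (to within
    1e-12) with the last included member is added as a conservative
    superset.
    """
    pps = np.asarray(pps, dtype=float)
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    if not np.isclose(pps.sum(), 1.0, atol=1e-6):
        raise ValueError("posterior probabilities must sum to 1")
    if ids is None:
        ids = np.array([f"variant_{i + 1}" for i in range(len(pps))], dtype=object)
    ids = np.asarray(ids, dtype=object)
    order = np.argsort(-pps, kind="stable")
    cum = np.cumsum(pps[order])
    n_take = int(np.searchsorted(cum, level - 1e-12) + 1)
    n_take = min(n_take, len(pps))
    if include_ties:
        boundary = pps[order[n_take - 1]]
        while n_take < len(pps) and abs(pps[order[n_take]] - boundary) <= 1e-12:
            n_take += 1
    chosen = order[:n_take]
    return CredibleSet(
        level=level,
        members=tuple(str(ids[i]) for i in chosen),
        member_pps=tuple(float(pps[i]) for i in chosen),
        cum_pp=float(pps[chosen].sum()),
    )


def shared_credible_variants(sets: dict[str, CredibleSet]) -> list[str]:
    """Variants common to every ancestry's credible set, by mean PP descending.

    An empty intersection is a valid outcome and yields an empty list.
    """
    if len(sets) < 2:
        raise ValueError("at least two credible sets are required")
    values = list(sets.values())
    shared = set(values[0].members)
    for cs in values[1:]:
        shared &= set(cs.members)
    if not shared:
        return []
    mean_pp = {
        v: float(
            np.mean([cs.member_pps[cs.members.index(v)] for cs in values])
        )
        for v in shared
    }
    return sorted(shared, key=lambda v: (-mean_pp[v], v))


def finemap_region(
    ids: np.ndarray,
    beta: np.ndarray | None = None,
    se: np.ndarray | None = None,
    p: np.ndarray | None = None,
    n: np.ndarray | None = None,
    maf: np.ndarray | None = None,
    prior_w: float = DEFAULT_PRIOR_W,
    level: float = DEFAULT_LEVEL,
) -> tuple[pd.DataFrame, CredibleSet]:
    """Fine-map one region from summary statistics.

    Uses beta/se when both are given, otherwise the p-value route (which
    then requires ``n`` and ``maf``).  Returns the per-variant table
    (ID, LOG_BF, PP, IN_CS95) and the credible set.
    """
    ids = np.asarray(ids, dtype=object)
    if beta is not None and se is not None:
        log_bf = np.asarray(abf_from_summary(beta, se, prior_w=prior_w))
    elif p is not None and n is not None and maf is not None:
        log_bf = np.asarray(abf_from_pvalue(p, n, maf, prior_w=prior_w))
    else:
        raise ValueError("provide beta+se, or p+n+maf")
    pps = posterior_probs(log_bf)
    cs = credible_set(pps, level=level, ids=ids)
    in_cs = np.isin(ids.astype(str), np.array(cs.members, dtype=str))
    table = pd.DataFrame(
        {"ID": ids, "LOG_BF": log_bf, "PP": pps, "IN_CS95": in_cs}
    )
    return table, cs
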