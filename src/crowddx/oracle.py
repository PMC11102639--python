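"""Exact plurality accuracy under a multinomial vote model.

Each group member votes independently, drawing one label from a fixed
categorical distribution whose first label is the correct diagnosis. The
plurality rule picks a label with maximal vote count, breaking ties uniformly
at random; its expected accuracy is therefore

    sum over count vectors (n_1, ..., n_m), sum n_i = k, of
        Multinomial(n; k, p) * 1[n_1 in argmax] / |argmax|

computed here by complete enumeration. This serves as the independent oracle
for the Monte-Carlo group-simulation engine, and formalizes the two drivers
of plurality performance: the per-vote accuracy p_1 and how concentrated the
remaining mass is on a single wrong label (error correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = ["VoteDistribution", "exact_plurality_accuracy", "binary_majority_accuracy"]

_ENUMERATION_GUARD = 10_000_000  # max count vectors enumerated


@dataclass(frozen=True)
class VoteDistribution:
    """Categorical per-vote distribution; ``probs[0]`` is the correct label.

    ``labels`` is optional cosmetics for reporting; probabilities must be
    non-negative and sum to 1 (tolerance 1e-12).
    """

    probs: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if len(probs) < 2:
            raise ValueError("need at least 2 labels (one correct, one wrong)")
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {sum(probs)!r}, not 1")
        if self.labels is not None and len(self.labels) != len(probs):
            raise ValueError("labels/probs length mismatch")

    @property
    def m(self) -> int:
        return len(self.probs)


def _count_vectors(k: int, m: int):
    """Yield all (n_1..n_m) with sum k, via stars-and-bars."""
    for bars in combinations_with_replacement(range(m), k):
        counts = [0] * m
        for b in bars:
            counts[b] += 1
        yield counts


def exact_plurality_accuracy(dist: VoteDistribution | Sequence[float], k: int) -> float:
    """Exact probability that plurality over ``k`` i.i.d. votes is correct.

    Ties receive credit ``1/|argmax|`` — the expectation of uniform random
    tie-breaking. Exact up to floating point; raises for enumerations larger
    than the internal guard (``C(k+m-1, m-1)`` count vectors).
    """
    if not isinstance(dist, VoteDistribution):
        dist = VoteDistribution(tuple(dist))
    if k < 1:
        raise ValueError("k must be >= 1")
    m = dist.m
    n_vectors = math.comb(k + m - 1, m - 1)
    if n_vectors > _ENUMERATION_GUARD:
        raise ValueError(
            f"enumeration of {n_vectors} count vectors exceeds guard ({_ENUMERATION_GUARD})"
        )
    counts = np.fromiter(
        (c for vec in _count_vectors(k, m) for c in vec), dtype=np.int64
    ).reshape(-1, m)
    top = counts.max(axis=1)
    win = counts[:, 0] == top
    counts = counts[win]
    if counts.size == 0:
        return 0.0
    n_tied = (counts == counts.max(axis=1, keepdims=True)).sum(axis=1)
    p = np.asarray(dist.probs)
    # multinomial log-pmf; a zero-probability label contributes 0 unless voted for
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = counts * np.log(p)
    logp[counts == 0] = 0.0
    log_pmf = (
        gammaln(k + 1) - gammaln(counts + 1).sum(axis=1) + logp.sum(axis=1)
    )
    return float(np.sum(np.exp(log_pmf) / n_tied))


def binary_majority_accuracy(p: float, k: int) -> float:
    """Condorcet majority accuracy: P(Binomial(k, p) > k/2) for odd ``k``.

    Strictly increasing in odd ``k`` when ``p > 1/2`` and strictly decreasing
    when ``p < 1/2``. Even ``k`` is rejected (a tie rule would be needed; use
    :func:`exact_plurality_accuracy` instead).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    return float(stats.binom.sf(k // 2, k, p))
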