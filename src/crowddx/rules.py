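"""Collective-intelligence aggregation rules for a single group ballot.

Five rules, each mapping one group's diagnoses of one case to a single
collective diagnosis:

- ``plurality``: the most common diagnosis; ties broken uniformly at random
  among the tied diagnoses.
- ``confidence`` / ``seniority``: the diagnosis of the member with the
  highest confidence / most years of experience; ties on the maximal weight
  broken uniformly at random among the tied members.
- ``confidence3`` / ``seniority3``: plurality among the 3 most confident /
  most senior members.

These scalar functions are the reference semantics; the vectorized engine in
:mod:`crowddx.groups` is cross-checked against them. All are pure functions
of ``(ballot, rng)``. Weights are compared only within a ballot, never across
studies (confidence scales differ between studies).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GroupBallot",
    "plurality",
    "max_weight_select",
    "top_m_plurality",
    "RULES",
    "apply_rule",
]


@dataclass(frozen=True)
class GroupBallot:
    """One virtual group's responses to one case in one condition."""

    gp_ids: tuple[str, ...]
    diagnoses: tuple[str, ...]
    confidences: tuple[float, ...] | None = None
    seniorities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.gp_ids)
        if n == 0:
            raise ValueError("ballot must have at least one member")
        for attr in ("diagnoses", "confidences", "seniorities"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ValueError(f"{attr} length {len(v)} != {n} members")

    def __len__(self) -> int:
        return len(self.gp_ids)

    def weights(self, weight_field: str) -> tuple[float, ...]:
        w = {"confidence": self.confidences, "seniority_years": self.seniorities}.get(
            weight_field
        )
        if weight_field not in ("confidence", "seniority_years"):
            raise ValueError(f"unknown weight field {weight_field!r}")
        if w is None or any(x is None or np.isnan(x) for x in w):
            raise ValueError(f"ballot is missing {weight_field} for some member")
        return w


def _as_labels(ballot: GroupBallot | Sequence[str]) -> Sequence[str]:
    return ballot.diagnoses if isinstance(ballot, GroupBallot) else list(ballot)


def plurality(ballot: GroupBallot | Sequence[str], rng: np.random.Generator) -> str:
    """Most common diagnosis; uniform random draw among tied modal labels."""
    labels = _as_labels(ballot)
    if len(labels) == 0:
        raise ValueError("ballot must have at least one member")
    counts = Counter(labels)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def max_weight_select(
    ballot: GroupBallot, weight_field: str, rng: np.random.Generator
) -> str:
    """Diagnosis of the member with maximal weight; member-level uniform
    tie-breaking on the maximal weight."""
    w = ballot.weights(weight_field)
    top = max(w)
    tied = [i for i, x in enumerate(w) if x == top]
    i = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
    return ballot.diagnoses[i]


def top_m_plurality(
    ballot: GroupBallot, weight_field: str, m: int, rng: np.random.Generator
) -> str:
    """Plurality among the ``m`` highest-weighted members.

    Members strictly above the m-th weight are always included; remaining
    slots are filled uniformly at random from the members tied at the
    boundary weight.
    """
    if not 1 <= m <= len(ballot):
        raise ValueError(f"m={m} out of range for group size {len(ballot)}")
    w = ballot.weights(weight_field)
    order = sorted(range(len(w)), key=lambda i: -w[i])
    boundary = w[order[m - 1]]
    sure = [i for i in order if w[i] > boundary]
    border = [i for i in order if w[i] == boundary]
    n_slots = m - len(sure)
    if n_slots < len(border):
        pick = rng.choice(len(border), size=n_slots, replace=False)
        chosen = sure + [border[int(j)] for j in pick]
    else:
        chosen = sure + border
    return plurality([ballot.diagnoses[i] for i in chosen], rng)


def _conf_rule(b: GroupBallot, rng: np.random.Generator) -> str:
    return max_weight_select(b, "confidence", rng)


def _sen_rule(b: GroupBallot, rng: np.random.Generator) -> str:
    return max_weight_select(b, "seniority_years", rng)


def _conf3_rule(b: GroupBallot, rng: np.random.Generator) -> str:
    return top_m_plurality(b, "confidence", min(3, len(b)), rng)


def _sen3_rule(b: GroupBallot, rng: np.random.Generator) -> str:
    return top_m_plurality(b, "seniority_years", min(3, len(b)), rng)


#: Registry of named rules, each ``(ballot, rng) -> diagnosis``.
RULES: dict[str, Callable[[GroupBallot, np.random.Generator], str]] = {
    "plurality": plurality,
    "confidence": _conf_rule,
    "seniority": _sen_rule,
    "confidence3": _conf3_rule,
    "seniority3": _sen3_rule,
}


def apply_rule(name: str, ballot: GroupBallot, rng: np.random.Generator) -> str:
    try:
        fn = RULES[name]
    except KeyError:
        raise KeyError(f"unknown rule {name!r}; available: {sorted(RULES)}") from None
    return fn(ballot, rng)
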