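"""Virtual-group construction and collective-decision simulation.

For each (condition, group size k) cell, all ``C(n, k)`` unique member
combinations are enumerated — unless that count exceeds a cap (default
6,000), in which case the cap's worth of distinct groups is sampled
uniformly without replacement. Each group then decides every case of its
condition under each aggregation rule.

The per-cell engine is vectorized over groups; its outputs are cross-checked
in the test suite against the scalar reference rules in
:mod:`crowddx.rules`. Tie-break randomness comes from generator streams
derived deterministically from ``(master seed, condition, k, rule, case)``,
so decisions do not depend on the ordering of the input records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnswerKey
from .rules import RULES

__all__ = ["VirtualGroupSet", "build_groups", "run_rules", "simulate_virtual_groups", "DEFAULT_CAP", "DEFAULT_K_RANGE"]

DEFAULT_CAP = 6000
DEFAULT_K_RANGE = range(3, 10)  # group sizes 3..9 inclusive


@dataclass(frozen=True)
class VirtualGroupSet:
    """Unique k-member combinations for one (condition, group size) cell."""

    condition: str
    k: int
    groups: tuple[tuple[str, ...], ...]
    sampled_flag: bool  # True when the cap forced sampling instead of enumeration

    def __post_init__(self) -> None:
        if any(len(set(g)) != self.k for g in self.groups):
            raise ValueError("every group must contain exactly k distinct members")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("groups must be distinct")

    def __len__(self) -> int:
        return len(self.groups)


def build_groups(
    member_ids: Sequence[str],
    k: int,
    cap: int = DEFAULT_CAP,
    rng: np.random.Generator | None = None,
    condition: str = "",
) -> VirtualGroupSet:
    """Enumerate or sample the unique k-member groups from ``member_ids``.

    Exhaustive enumeration when ``C(n, k) <= cap``; otherwise ``cap``
    distinct member sets are sampled uniformly (rejection sampling on
    canonical sorted tuples). Deterministic given ``rng``.
    """
    ids = sorted(set(member_ids))
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"group size k={k} out of range for {n} members")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n_total = math.comb(n, k)
    if n_total <= cap:
        groups = tuple(combinations(ids, k))
        return VirtualGroupSet(condition=condition, k=k, groups=groups, sampled_flag=False)
    if rng is None:
        raise ValueError(f"C({n},{k})={n_total} exceeds cap={cap}; an rng is required for sampling")
    chosen: set[tuple[str, ...]] = set()
    while len(chosen) < cap:
        draw = rng.choice(n, size=k, replace=False)
        draw.sort()
        chosen.add(tuple(ids[i] for i in draw))
    return VirtualGroupSet(
        condition=condition, k=k, groups=tuple(sorted(chosen)), sampled_flag=True
    )


# -- vectorized per-cell engine ---------------------------------------------


def _cell_matrices(records: pd.DataFrame, groupset: VirtualGroupSet):
    """Pivot one condition's records into dense (GP x case) matrices."""
    sub = records[records["condition"] == groupset.condition]
    if sub.empty:
        raise ValueError(f"no records for condition {groupset.condition!r}")
    members = sorted({m for g in groupset.groups for m in g})
    missing_members = set(members) - set(sub["gp_id"])
    if missing_members:
        raise ValueError(
            f"group member(s) {sorted(missing_members)} have no records in "
            f"condition {groupset.condition!r}"
        )
    sub = sub[sub["gp_id"].isin(members)]
    cases = sorted(sub["case_id"].unique())
    diag = sub.pivot_table(
        index="gp_id", columns="case_id", values="diagnosis_std", aggfunc="first"
    ).reindex(index=members, columns=cases)
    if diag.isna().any().any():
        gp = diag.index[diag.isna().any(axis=1)][0]
        case = diag.columns[diag.loc[gp].isna()][0]
        raise ValueError(
            f"member {gp!r} has no record for case {case!r} in condition "
            f"{groupset.condition!r}"
        )
    conf = (
        sub.pivot_table(index="gp_id", columns="case_id", values="confidence", aggfunc="first")
        .reindex(index=members, columns=cases)
        .to_numpy(dtype=float)
    )
    sen = (
        sub.pivot_table(index="gp_id", columns="case_id", values="seniority_years", aggfunc="first")
        .reindex(index=members, columns=cases)
        .to_numpy(dtype=float)
    )
    member_index = {m: i for i, m in enumerate(members)}
    M = np.array([[member_index[m] for m in g] for g in groupset.groups], dtype=np.int64)
    return cases, diag, conf, sen, M


def _plurality_codes(votes: np.ndarray, n_labels: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized plurality with uniform tie-breaking; ``votes`` is (G, k)
    label codes, returns (G,) winning codes."""
    G = votes.shape[0]
    counts = np.zeros((G, n_labels), dtype=np.int64)
    np.add.at(counts, (np.arange(G)[:, None], votes), 1)
    # jitter < 1 never reorders distinct counts; uniform among tied maxima
    return np.argmax(counts + rng.random((G, n_labels)) * 0.5, axis=1)


def _max_weight_codes(
    votes: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if np.isnan(weights).any():
        raise ValueError("weight-based rule applied to a member with a missing weight")
    mask = weights == weights.max(axis=1, keepdims=True)
    sel = np.argmax(rng.random(weights.shape) * mask, axis=1)
    return votes[np.arange(votes.shape[0]), sel]


def _top_m_codes(
    votes: np.ndarray,
    weights: np.ndarray,
    m: int,
    n_labels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if np.isnan(weights).any():
        raise ValueError("weight-based rule applied to a member with a missing weight")
    # random member shuffle + stable sort on weight = uniform order among ties
    perm = rng.random(weights.shape).argsort(axis=1)
    w_perm = np.take_along_axis(weights, perm, axis=1)
    order = np.argsort(-w_perm, axis=1, kind="stable")
    top = np.take_along_axis(perm, order[:, :m], axis=1)
    return _plurality_codes(np.take_along_axis(votes, top, axis=1), n_labels, rng)


def _rule_codes(
    rule: str,
    votes: np.ndarray,
    conf: np.ndarray,
    sen: np.ndarray,
    n_labels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    k = votes.shape[1]
    if rule == "plurality":
        return _plurality_codes(votes, n_labels, rng)
    if rule == "confidence":
        return _max_weight_codes(votes, conf, rng)
    if rule == "seniority":
        return _max_weight_codes(votes, sen, rng)
    if rule == "confidence3":
        return _top_m_codes(votes, conf, min(3, k), n_labels, rng)
    if rule == "seniority3":
        return _top_m_codes(votes, sen, min(3, k), n_labels, rng)
    raise KeyError(f"unknown rule {rule!r}; available: {sorted(RULES)}")


def run_rules(
    records: pd.DataFrame,
    groupset: VirtualGroupSet,
    rules: Sequence[str],
    key: AnswerKey,
    seed: int = 0,
) -> pd.DataFrame:
    """Apply each rule to every group x case of one (condition, k) cell.

    ``records`` must be standardized and scored. Returns one decision row per
    group x case x rule with columns
    ``condition, k, group_id, case_id, rule, diagnosis, correct``.
    Weight-based rules require confidence/seniority for every member.
    """
    for rule in rules:
        if rule not in RULES:
            raise KeyError(f"unknown rule {rule!r}; available: {sorted(RULES)}")
    if records["diagnosis_std"].isna().any():
        raise ValueError("records must be standardized before group simulation")
    cases, diag, conf, sen, M = _cell_matrices(records, groupset)
    cond_codes = sorted(records["condition"].unique())
    cond_index = cond_codes.index(groupset.condition)
    rule_order = sorted(RULES)
    G = len(groupset.groups)

    frames = []
    for case_index, case in enumerate(cases):
        if case not in key:
            raise KeyError(f"case {case!r} absent from answer key")
        col = pd.unique(diag[case].to_numpy())
        labels = list(col)
        code_of = {lab: i for i, lab in enumerate(labels)}
        codes_gp = diag[case].map(code_of).to_numpy(dtype=np.int64)
        votes = codes_gp[M]  # (G, k)
        conf_case = conf[:, case_index][M]
        sen_case = sen[:, case_index][M]
        correct_code = code_of.get(key[case], -1)
        for rule in rules:
            rng = np.random.default_rng(
                [seed, cond_index, groupset.k, rule_order.index(rule), case_index]
            )
            winners = _rule_codes(rule, votes, conf_case, sen_case, len(labels), rng)
            frames.append(
                pd.DataFrame(
                    {
                        "condition": groupset.condition,
                        "k": groupset.k,
                        "group_id": np.arange(G),
                        "case_id": case,
                        "rule": rule,
                        "diagnosis": pd.Categorical.from_codes(
                            winners, categories=labels
                        ).astype(str),
                        "correct": winners == correct_code,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    for col in ("condition", "case_id", "rule", "diagnosis"):
        out[col] = out[col].astype("category")
    return out


def simulate_virtual_groups(
    records: pd.DataFrame,
    key: AnswerKey,
    rules: Sequence[str] = tuple(sorted(RULES)),
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Full driver: build groups and run rules for every condition x k.

    Groups are formed within condition only (GPs have records only in their
    own condition under a between-subject design; within-subject groups
    decide each condition's own case set). Group sampling in cells over the
    cap uses an independent stream per cell.
    """
    decisions = []
    conditions = sorted(records["condition"].unique())
    for cond_index, condition in enumerate(conditions):
        members = sorted(records.loc[records["condition"] == condition, "gp_id"].unique())
        for k in k_range:
            rng = np.random.default_rng([seed, 104_729, cond_index, k])
            groupset = build_groups(members, k, cap=cap, rng=rng, condition=condition)
            decisions.append(run_rules(records, groupset, rules, key, seed=seed))
    out = pd.concat(decisions, ignore_index=True)
    for col in ("condition", "case_id", "rule", "diagnosis"):
        out[col] = out[col].astype("category")
    return out
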