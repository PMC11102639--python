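"""Summaries of collective decisions.

Four analyses: accuracy-vs-group-size curves per rule and condition, the
case-level view ordered by case difficulty, absolute accuracy gains against
the control-condition individual baseline (comparing pooling with a
decision-support system, DSS), and the plurality x DSS synergy. Plus the
descriptive accuracy-by-confidence / accuracy-by-seniority-band summaries.

Averaging order is groups -> per-case mean -> unweighted mean over cases
(cases as the unit of presentation); pooled-group weighting is available as
a sensitivity option. Monte-Carlo standard errors accompany every curve
point because cells above the group cap are sampled, not enumerated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "accuracy_curves",
    "case_level",
    "dss_gain",
    "synergy",
    "association_summaries",
    "SENIORITY_BANDS",
]

#: Seniority bands used in descriptive summaries (years of experience).
SENIORITY_BANDS = ((-np.inf, 10, "<=10"), (10, 20, "11-20"), (20, np.inf, ">=21"))


def individual_accuracy(records: pd.DataFrame, weighting: str = "case") -> pd.Series:
    """Mean individual accuracy per condition (the group-size-1 baseline)."""
    correct = records["correct"].astype(float)
    if weighting == "case":
        per_case = correct.groupby(
            [records["condition"], records["case_id"]], observed=True
        ).mean()
        return per_case.groupby(level=0, observed=True).mean()
    if weighting == "pooled":
        return correct.groupby(records["condition"], observed=True).mean()
    raise ValueError(f"unknown weighting {weighting!r}")


def accuracy_curves(
    decisions: pd.DataFrame,
    records: pd.DataFrame,
    weighting: str = "case",
) -> pd.DataFrame:
    """Mean accuracy per rule x condition x group size, with k=1 baseline.

    Group decisions are averaged within case and then unweighted across
    cases (``weighting="case"``) or pooled over all group x case decisions
    (``weighting="pooled"``). A k=1 row per rule carries the individual
    baseline of its condition. Columns:
    ``rule, condition, k, accuracy, mc_se, n_groups``.
    """
    if weighting not in ("case", "pooled"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = []
    per_case = (
        decisions.assign(correct=decisions["correct"].astype(float))
        .groupby(["rule", "condition", "k", "case_id"], observed=True)["correct"]
        .agg(["mean", "var", "count"])
        .reset_index()
    )
    for (rule, condition, k), sub in per_case.groupby(
        ["rule", "condition", "k"], observed=True
    ):
        if weighting == "case":
            acc = sub["mean"].mean()
            # independent MC error per case mean, averaged
            se = float(np.sqrt(np.nansum(sub["var"] / sub["count"])) / len(sub))
        else:
            acc = float(np.average(sub["mean"], weights=sub["count"]))
            se = float(
                np.sqrt(np.nansum(sub["var"] * sub["count"])) / sub["count"].sum()
            )
        rows.append(
            {
                "rule": rule,
                "condition": condition,
                "k": int(k),
                "accuracy": float(acc),
                "mc_se": se,
                "n_groups": int(sub["count"].max()),
            }
        )

    baseline = individual_accuracy(records, weighting)
    n_ind = records.groupby("condition", observed=True)["correct"].count()
    ind_per_case = (
        records.assign(correct=records["correct"].astype(float))
        .groupby(["condition", "case_id"], observed=True)["correct"]
        .agg(["mean", "var", "count"])
    )
    for rule in sorted(decisions["rule"].unique()):
        for condition, acc in baseline.items():
            sub = ind_per_case.loc[condition]
            if weighting == "case":
                se = float(np.sqrt(np.nansum(sub["var"] / sub["count"])) / len(sub))
            else:
                se = float(
                    np.sqrt(np.nansum(sub["var"] * sub["count"])) / sub["count"].sum()
                )
            rows.append(
                {
                    "rule": rule,
                    "condition": condition,
                    "k": 1,
                    "accuracy": float(acc),
                    "mc_se": se,
                    "n_groups": int(n_ind[condition]),
                }
            )
    out = pd.DataFrame(rows).sort_values(["rule", "condition", "k"]).reset_index(drop=True)
    return out


def case_level(decisions: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per-case diagnostics ordered by control-condition case difficulty.

    Columns: ``case_id, condition, difficulty`` (1 - mean individual
    accuracy), ``modal_correct`` (is the correct label the strictly most
    frequent individual response?), ``modal_wrong_share`` (share of the most
    frequent wrong label among all wrong responses; missing when a case has
    no errors) and one ``plurality_k{k}`` accuracy column per simulated
    group size. Rows are ordered by mean individual accuracy in the control
    condition, descending (easiest first); cases never diagnosed in the
    control condition fall back to their own condition's accuracy.
    """
    rows = []
    for (condition, case), sub in records.groupby(["condition", "case_id"], observed=True):
        correct = sub["correct"].astype(bool)
        acc = float(correct.mean())
        n_correct = int(correct.sum())
        wrong = sub.loc[~correct, "diagnosis_std"]
        if len(wrong):
            wrong_counts = wrong.value_counts()
            modal_wrong_share = float(wrong_counts.iloc[0] / len(wrong))
            modal_correct = n_correct > int(wrong_counts.iloc[0])
        else:
            modal_wrong_share = np.nan
            modal_correct = True
        rows.append(
            {
                "case_id": case,
                "condition": condition,
                "mean_individual_accuracy": acc,
                "difficulty": 1.0 - acc,
                "modal_correct": modal_correct,
                "modal_wrong_share": modal_wrong_share,
            }
        )
    out = pd.DataFrame(rows)

    plur = decisions[decisions["rule"] == "plurality"]
    acc_k = (
        plur.assign(correct=plur["correct"].astype(float))
        .groupby(["condition", "case_id", "k"], observed=True)["correct"]
        .mean()
        .unstack("k")
    )
    acc_k.columns = [f"plurality_k{int(k)}" for k in acc_k.columns]
    out = out.merge(acc_k.reset_index(), on=["condition", "case_id"], how="left")

    control_acc = out.loc[out["condition"] == "control"].set_index("case_id")[
        "mean_individual_accuracy"
    ]
    order_key = out["case_id"].map(control_acc)
    order_key = order_key.fillna(out["mean_individual_accuracy"])
    out = (
        out.assign(_order=order_key)
        .sort_values(["_order", "case_id", "condition"], ascending=[False, True, True])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return out


def dss_gain(curves: pd.DataFrame) -> pd.DataFrame:
    """Absolute accuracy increase over the control-condition individual
    baseline, per rule x condition x k.

    The DSS conditions' k=1 rows give the DSS baselines (what a single GP
    gains from the DSS alone). Requires a control k=1 row.
    """
    base_rows = curves[(curves["condition"] == "control") & (curves["k"] == 1)]
    if base_rows.empty:
        raise ValueError("curves lack a control-condition k=1 baseline row")
    baseline = float(base_rows["accuracy"].iloc[0])
    out = curves.copy()
    out["gain"] = out["accuracy"] - baseline
    return out[["rule", "condition", "k", "accuracy", "gain"]]


def synergy(curves: pd.DataFrame, rule: str = "plurality") -> pd.DataFrame:
    """Per-k difference ``rule(DSS condition) - rule(control)``.

    Positive values mean pooling helps more (or accuracy is simply higher)
    when members used the DSS; an upward trend in k indicates the pooling
    benefit itself grows with the DSS.
    """
    sub = curves[curves["rule"] == rule]
    control = sub[sub["condition"] == "control"].set_index("k")["accuracy"]
    if control.empty:
        raise ValueError(f"no control-condition curve for rule {rule!r}")
    rows = []
    for condition in sorted(set(sub["condition"]) - {"control"}):
        dss = sub[sub["condition"] == condition].set_index("k")["accuracy"]
        common = control.index.intersection(dss.index)
        for k in sorted(common):
            rows.append(
                {
                    "rule": rule,
                    "condition": condition,
                    "k": int(k),
                    "synergy": float(dss[k] - control[k]),
                }
            )
    return pd.DataFrame(rows, columns=["rule", "condition", "k", "synergy"])


def seniority_band(years: pd.Series) -> pd.Series:
    bins = [b[0] for b in SENIORITY_BANDS] + [np.inf]
    labels = [b[2] for b in SENIORITY_BANDS]
    return pd.cut(years, bins=bins, labels=labels)


def association_summaries(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Binned accuracy by confidence level and by seniority band.

    Returns ``{"confidence": ..., "seniority": ...}``; each table has the
    bin, mean accuracy, standard error of the mean, and observation count.
    Seniority bands are <=10, 11-20, >=21 years.
    """
    correct = records["correct"].astype(float)

    def _summarize(by: pd.Series, name: str) -> pd.DataFrame:
        g = correct.groupby(by, observed=False).agg(["mean", "std", "count"])
        g["se"] = g["std"] / np.sqrt(g["count"].clip(lower=1))
        g = g.drop(columns="std").rename(columns={"mean": "accuracy", "count": "n"})
        g.index.name = name
        return g.reset_index()

    conf = _summarize(records["confidence"], "confidence")
    conf = conf[conf["n"] > 0].reset_index(drop=True)
    sen = _summarize(seniority_band(records["seniority_years"]), "seniority_band")
    return {"confidence": conf, "seniority": sen}
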