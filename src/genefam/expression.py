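"""qRT-PCR analysis: relative expression, induction calling, tissue profiles.

Relative expression uses the 2^-ddCt model with amplification efficiency
fixed at 2: expression = 2^-((Ct_target - Ct_reference) - calibrator_delta),
the calibrator being the 0-h control (treatment design) or the tissue
median (tissue design). Induction calling compares treated vs control
replicates with a two-sample Student's t-test (pooled variance by
default, Welch optional) on log2 expression; a gene x condition x
timepoint is called induced iff P < 0.05 and log2 fold change >= 1
(the fold-change boundary is inclusive, the P boundary exclusive).
Raw p-values are reported by default; Benjamini-Hochberg adjustment is
available but off, matching the conventional single-gene qPCR workflow.

Tissue profiles are log2(expression / median across the gene's tissues);
the median over an even tissue count is the mean of the two central
values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

P_THRESHOLD = 0.05
LOG2FC_THRESHOLD = 1.0

QPCR_COLUMNS = [
    "gene_id",
    "condition",
    "timepoint_h",
    "replicate",
    "ct_target",
    "ct_reference",
]


@dataclass(frozen=True)
class InductionCall:
    gene_id: str
    condition: str
    timepoint_h: float
    log2fc: float
    p_value: float
    induced: bool


def relative_expression(
    ct_target: float, ct_reference: float, calibrator_delta: float = 0.0
) -> float:
    """2^-ddCt fold value for one well."""
    for v in (ct_target, ct_reference, calibrator_delta):
        if not math.isfinite(v):
            raise ValidationError("Ct values must be finite")
    return 2.0 ** (-((ct_target - ct_reference) - calibrator_delta))


def _t_test(
    log2_treated: np.ndarray, log2_control: np.ndarray, welch: bool = False
) -> float:
    if log2_treated.std(ddof=1) == 0.0 and log2_control.std(ddof=1) == 0.0:
        return 1.0 if log2_treated.mean() == log2_control.mean() else 0.0
    res = stats.ttest_ind(log2_treated, log2_control, equal_var=not welch)
    return float(res.pvalue)


def test_induction(
    samples_treated: Sequence[float],
    samples_control: Sequence[float],
    gene_id: str = "",
    condition: str = "",
    timepoint_h: float = float("nan"),
    welch: bool = False,
) -> InductionCall:
    """Induction call from replicate relative-expression values.

    Inputs are positive linear fold values; the t-test and the fold
    change are computed on the log2 scale.
    """
    t = np.asarray(samples_treated, dtype=float)
    c = np.asarray(samples_control, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValidationError("need >= 2 replicates per group")
    if (t <= 0).any() or (c <= 0).any() or not (
        np.isfinite(t).all() and np.isfinite(c).all()
    ):
        raise ValidationError("expression values must be positive and finite")
    lt, lc = np.log2(t), np.log2(c)
    log2fc = float(lt.mean() - lc.mean())
    p = _t_test(lt, lc, welch=welch)
    induced = (p < P_THRESHOLD) and (log2fc >= LOG2FC_THRESHOLD)
    return InductionCall(gene_id, condition, timepoint_h, log2fc, p, induced)


def tissue_profile(values: Sequence[float]) -> list[float]:
    """log2(value / median) across a gene's tissues (scale invariant)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("need >= 2 tissues")
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValidationError("expression values must be positive and finite")
    med = float(np.median(v))
    return [float(x) for x in np.log2(v / med)]


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns {missing}")
    cts = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    return table


def call_inductions(
    table: pd.DataFrame,
    control_timepoint: float = 0.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Per (gene, condition, timepoint) induction calls vs the 0-h control.

    Relative expression is computed per replicate as 2^-dCt (dCt =
    ct_target - ct_reference); the control group is the same gene and
    condition at ``control_timepoint``.
    """
    validate_qpcr_table(table)
    df = table.copy()
    df["log2_expr"] = -(df["ct_target"] - df["ct_reference"])
    rows = []
    for (gene, cond), grp in df.groupby(["gene_id", "condition"], sort=True):
        ctrl = grp[grp["timepoint_h"] == control_timepoint]["log2_expr"].to_numpy()
        if len(ctrl) < 2:
            raise ValidationError(
                f"{gene}/{cond}: need >= 2 control replicates at t={control_timepoint}"
            )
        for tp, tgrp in grp[grp["timepoint_h"] != control_timepoint].groupby(
            "timepoint_h", sort=True
        ):
            call = test_induction(
                2.0 ** tgrp["log2_expr"].to_numpy(),
                2.0 ** ctrl,
                gene_id=gene,
                condition=cond,
                timepoint_h=float(tp),
                welch=welch,
            )
            rows.append(
                {
                    "gene_id": call.gene_id,
                    "condition": call.condition,
                    "timepoint_h": call.timepoint_h,
                    "log2fc": call.log2fc,
                    "p_value": call.p_value,
                    "induced": call.induced,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "condition", "timepoint_h", "log2fc", "p_value", "induced"],
    )


def adjust_bh(calls: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini-Hochberg adjustment (off in the default workflow)."""
    out = calls.copy()
    out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    out["induced"] = (out["p_adjusted"] < P_THRESHOLD) & (
        out["log2fc"] >= LOG2FC_THRESHOLD
    )
    return out


def count_induced(calls: pd.DataFrame, condition: str) -> int:
    """Genes induced at ANY timepoint of a condition (each gene once)."""
    sub = calls[(calls["condition"] == condition) & calls["induced"]]
    return int(sub["gene_id"].nunique())


def count_induced_per_condition(calls: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"condition": c, "n_induced": count_induced(calls, c)}
            for c in sorted(calls["condition"].unique())
        ]
    )


def tissue_profile_table(table: pd.DataFrame) -> pd.DataFrame:
    """Median-centred log2 tissue profiles from a tissue-design Ct table.

    The ``condition`` column holds tissue labels; expression per tissue
    is the mean over replicates of 2^-dCt.
    """
    validate_qpcr_table(table)
    df = table.copy()
    df["expr"] = 2.0 ** -(df["ct_target"] - df["ct_reference"])
    mean_expr = (
        df.groupby(["gene_id", "condition"], sort=True)["expr"].mean().unstack()
    )
    centred = mean_expr.apply(
        lambda row: pd.Series(
            tissue_profile(row.to_numpy()), index=row.index
        ),
        axis=1,
    )
    centred.index.name = "gene_id"
    return centred
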