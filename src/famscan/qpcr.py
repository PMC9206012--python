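"""Relative expression from qPCR CT values via the 2^-ddCT method.

dCT(gene, condition) = mean CT(gene) - mean CT(reference gene) within the
condition; ddCT = dCT(condition) - dCT(calibrator condition); the fold
change is 2^-ddCT (amplification efficiency fixed at 2, the method's
assumption), so the calibrator condition has fold 1 by construction.
Per-replicate dCT values (replicate CT minus the condition's mean reference
CT) are retained and used for a two-sample t-test of each condition against
the calibrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ParameterError

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct")


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCT summary of one gene in one condition (vs the calibrator)."""

    gene: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float
    p_value: float
    flag: str  # ns | p05 | p01


def group_ttest(
    values_a, values_b, kind: str = "equal_var"
) -> Tuple[float, float, str]:
    """Two-sided two-sample t-test with significance flags.

    ``kind`` is ``equal_var`` (Student) or ``welch``. Flags: p05 at
    P <= 0.05, p01 at P <= 0.01 (inclusive), else ns. Identical groups give
    t = 0, p = 1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs >= 2 values")
    if kind not in ("equal_var", "welch"):
        raise ParameterError(f"unknown t-test kind {kind!r}")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0, "ns"
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=(kind == "equal_var"))
    t, p = float(t), float(p)
    if np.isnan(p):  # zero variance in both groups but different means
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0, "p01"
    return t, p, _flag(p)


def _flag(p: float) -> str:
    if p <= 0.01:
        return "p01"
    if p <= 0.05:
        return "p05"
    return "ns"


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
    ttest_kind: str = "equal_var",
) -> List[RelativeExpression]:
    """Relative expression of every non-reference gene in every condition.

    ``table`` needs columns gene, condition, replicate, ct. The reference
    gene must be measured in every condition and the calibrator condition
    must be present. The per-condition t-test compares replicate dCT values
    against the calibrator's; the calibrator row itself is reported with
    fold 1 and p = 1.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"CT table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ParameterError("CT values must be > 0")
    genes = sorted(table["gene"].unique())
    conditions = sorted(table["condition"].astype(str).unique())
    calibrator_condition = str(calibrator_condition)
    if reference_gene not in genes:
        raise ParameterError(f"reference gene {reference_gene!r} absent")
    if calibrator_condition not in conditions:
        raise ParameterError(f"calibrator {calibrator_condition!r} absent")

    ref_mean: Dict[str, float] = {}
    for cond in conditions:
        sub = table[(table["gene"] == reference_gene)
                    & (table["condition"].astype(str) == cond)]
        if sub.empty:
            raise ParameterError(
                f"reference gene {reference_gene!r} missing in condition {cond!r}"
            )
        ref_mean[cond] = float(sub["ct"].mean())

    results: List[RelativeExpression] = []
    for gene in genes:
        # per-condition replicate-level dCT (gene replicate CT - mean ref CT)
        rep_dct: Dict[str, np.ndarray] = {}
        for cond in conditions:
            sub = table[(table["gene"] == gene)
                        & (table["condition"].astype(str) == cond)]
            if sub.empty:
                continue
            rep_dct[cond] = sub["ct"].to_numpy(dtype=float) - ref_mean[cond]
        if calibrator_condition not in rep_dct:
            continue
        cal = rep_dct[calibrator_condition]
        cal_dct = float(cal.mean())
        for cond, vals in rep_dct.items():
            dct = float(vals.mean())
            dd = dct - cal_dct
            if cond == calibrator_condition:
                p, flag = 1.0, "ns"
            elif len(vals) >= 2 and len(cal) >= 2:
                _, p, flag = group_ttest(vals, cal, kind=ttest_kind)
            else:
                p, flag = float("nan"), "ns"
            results.append(
                RelativeExpression(
                    gene=gene, condition=cond, delta_ct=dct,
                    delta_delta_ct=dd, fold_change=float(2.0 ** (-dd)),
                    p_value=p, flag=flag,
                )
            )
    results.sort(key=lambda r: (r.gene, r.condition))
    return results
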