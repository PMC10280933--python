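"""Two-group differential expression on the log2 matrix.

Calls are made per gene with Welch's unequal-variance t-test on the log2
intensities and a fold-change gate computed from the difference of log2 group
means (a geometric-mean ratio, the microarray convention). Genes are labelled
``up`` when fold change >= ``fc_up`` and p < ``alpha``, ``down`` when fold
change <= ``fc_down`` and p < ``alpha``, ``ns`` otherwise; both boundaries are
inclusive. No multiple-testing correction is applied at this stage — the gate
is on the raw p-value, combined with the fold-change filter.

The test behind the comparison is an explicit design choice: moderated /
empirical-Bayes variants are out of scope and the Welch test is exposed on its
own so it can be checked against an exhaustive label-permutation oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

DIRECTIONS = ("up", "down", "ns")


def fold_change(case_values, control_values) -> float:
    """Linear fold change 2^(mean(case) - mean(control)) from log2 values."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    if not (np.isfinite(case_values).all() and np.isfinite(control_values).all()):
        raise ValueError("fold_change requires finite values")
    return float(2.0 ** (case_values.mean() - control_values.mean()))


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sided t-test; returns (t, p, Welch-Satterthwaite df).

    Degenerate zero-variance inputs follow a documented convention: if both
    groups have zero variance, p = 1.0 for equal means and p = 0.0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires >= 2 values per group")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0, float(x.size + y.size - 2)
        return float(np.inf) * np.sign(x.mean() - y.mean()), 0.0, float(
            x.size + y.size - 2)
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def _welch_vectorized(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values with the same zero-variance conventions."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    both_flat = (case.var(axis=1, ddof=1) == 0) & (control.var(axis=1, ddof=1) == 0)
    if both_flat.any():
        equal = np.isclose(case.mean(axis=1), control.mean(axis=1), rtol=0, atol=0)
        p[both_flat & equal] = 1.0
        p[both_flat & ~equal] = 0.0
    return p


def differential_expression(matrix: ExpressionMatrix, fc_up: float = 2.0,
                            fc_down: float = 0.5, alpha: float = 0.05
                            ) -> pd.DataFrame:
    """One record per gene: gene_id, biotype, fc, log2fc, p, direction.

    Output is deterministically ordered by (biotype, gene_id).
    """
    case = matrix.group_values("case")
    control = matrix.group_values("control")
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    fc = 2.0 ** log2fc
    p = _welch_vectorized(case, control)

    direction = np.full(len(fc), "ns", dtype=object)
    direction[(fc >= fc_up) & (p < alpha)] = "up"
    direction[(fc <= fc_down) & (p < alpha)] = "down"

    records = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "biotype": matrix.biotypes.to_numpy(),
        "fc": fc,
        "log2fc": log2fc,
        "p": p,
        "direction": direction,
    })
    return records.sort_values(["biotype", "gene_id"]).reset_index(drop=True)


def de_summary(records: pd.DataFrame) -> dict:
    """Up/down counts per biotype, mirroring the reporting shape of DE tables."""
    out: dict[str, int] = {}
    for biotype in sorted(records["biotype"].unique()):
        sub = records[records["biotype"] == biotype]
        for d in ("up", "down"):
            out[f"{biotype}_{d}"] = int((sub["direction"] == d).sum())
    return out


def differential_genes(records: pd.DataFrame, biotype: str | None = None
                       ) -> pd.DataFrame:
    """Rows called up or down, optionally restricted to one biotype."""
    sub = records[records["direction"] != "ns"]
    if biotype is not None:
        sub = sub[sub["biotype"] == biotype]
    return sub.reset_index(drop=True)
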