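"""Differential expression at the pipeline's two fold-change tiers.

Genes are tested case vs control with the Wilcoxon rank-sum test
(Mann-Whitney; the signed-rank variant when the design is declared
paired), fold changes are taken as differences of group means on log2
scale, and the false discovery rate is controlled by Benjamini-Hochberg
across the tested genes.  Two categorical calls are derived: the DEG call
(FC > 1.3 and FDR < 0.01) and the heatmap call (|log2FC| > 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from warburgph.core_io import ExpressionMatrix, ValidationError
from warburgph.preprocess import ExpressionThreshold, expressed_mask

DEG_FC = 1.3
DEG_FDR = 0.01
HEATMAP_LOG2FC = 0.6

#: below this total sample count the rank-sum p-value is computed by exact
#: enumeration; above it, by the normal approximation with tie correction
EXACT_N_MAX = 12


@dataclass
class DifferentialResult:
    """Per-gene differential-expression table.

    ``table`` columns: mean_case, mean_control (log2), log2FC, FC
    (= 2**log2FC), p_value, q_value, deg_call, heatmap_call, expressed.
    Genes not expressed in either group keep NaN statistics and the
    ``not_expressed`` category.
    """

    table: pd.DataFrame
    paired: bool
    n_case: int
    n_control: int

    def calls(self, kind: str = "deg_call") -> pd.Series:
        return self.table[kind]

    def fold_change(self, gene: str) -> float:
        return float(self.table.at[gene, "FC"])


def _rank_sum_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    n_tot = len(case) + len(ctrl)
    pooled = np.concatenate([case, ctrl])
    if np.all(pooled == pooled[0]):  # fully tied: no evidence either way
        return 1.0
    has_ties = len(np.unique(pooled)) < n_tot
    if n_tot <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(res.pvalue)


def _signed_rank_p(case: np.ndarray, ctrl: np.ndarray) -> float:
    diff = case - ctrl
    if np.all(diff == 0):
        return 1.0
    mode = "exact" if len(diff) <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(case, ctrl, alternative="two-sided", method=mode, zero_method="wilcox")
    return float(res.pvalue)


def differential_expression(
    mat: ExpressionMatrix,
    threshold: ExpressionThreshold | float | None = None,
    fc_on_linear_means: bool = False,
) -> DifferentialResult:
    """Test every expressed gene case vs control.

    Parameters
    ----------
    mat
        Expression matrix with both groups non-empty.  If ``mat.paired``
        is set the groups must be equal-sized and index-matched and the
        signed-rank test is used; otherwise the unpaired rank-sum test.
    threshold
        Optional expressed-gene cut; genes below it in both groups are
        excluded from testing (and from the FDR correction).
    fc_on_linear_means
        If True, FC is the ratio of linear-scale group means instead of
        2**(difference of log2 means); a sensitivity-analysis option.
    """
    mat.require_two_groups()
    case_ids, ctrl_ids = mat.case_samples, mat.control_samples
    if mat.paired and len(case_ids) != len(ctrl_ids):
        raise ValidationError("paired design requires equal group sizes")

    case = mat.values[case_ids].to_numpy()
    ctrl = mat.values[ctrl_ids].to_numpy()
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)

    if fc_on_linear_means:
        lin_case = np.power(2.0, case).mean(axis=1)
        lin_ctrl = np.power(2.0, ctrl).mean(axis=1)
        fc = lin_case / lin_ctrl
        log2fc = np.log2(fc)
    else:
        log2fc = mean_case - mean_ctrl
        fc = np.power(2.0, log2fc)

    if threshold is None:
        expressed = pd.Series(True, index=mat.values.index)
    else:
        expressed = expressed_mask(mat, threshold)

    genes = mat.values.index
    pvals = np.full(len(genes), np.nan)
    test = _signed_rank_p if mat.paired else _rank_sum_p
    for i in np.flatnonzero(expressed.to_numpy()):
        pvals[i] = test(case[i], ctrl[i])

    qvals = np.full(len(genes), np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    deg_call = np.where(
        ~expressed,
        "not_expressed",
        np.where(
            (fc > DEG_FC) & (qvals < DEG_FDR),
            "up",
            np.where((fc < 1.0 / DEG_FC) & (qvals < DEG_FDR), "down", "unchanged"),
        ),
    )
    heatmap_call = np.where(
        ~expressed,
        "not_expressed",
        np.where(log2fc > HEATMAP_LOG2FC, "up", np.where(log2fc < -HEATMAP_LOG2FC, "down", "unchanged")),
    )

    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2FC": log2fc,
            "FC": fc,
            "p_value": pvals,
            "q_value": qvals,
            "deg_call": deg_call,
            "heatmap_call": heatmap_call,
            "expressed": expressed.to_numpy(),
        },
        index=genes,
    )
    return DifferentialResult(
        table=table, paired=mat.paired, n_case=len(case_ids), n_control=len(ctrl_ids)
    )


def categorize_for_heatmap(result: DifferentialResult, panel) -> pd.DataFrame:
    """One categorical row per panel gene: up / down / unchanged / not_expressed.

    Panel genes absent from the tested matrix are recorded as ``missing``.
    """
    rows = {}
    for gene in panel.gene_symbols():
        if gene in result.table.index:
            rows[gene] = result.table.at[gene, "heatmap_call"]
        else:
            rows[gene] = "missing"
    return pd.DataFrame({"call": rows})
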