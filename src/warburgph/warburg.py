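"""Two-criterion Warburg-effect classifier.

A case/control dataset is called Warburg-positive when

(i)  lactate dehydrogenase (LDHA or LDHB) AND a monocarboxylate lactate
     exporter (SLC16A1 or SLC16A3) are up-regulated more than two-fold in
     cases, and
(ii) the per-sample PDHB/PKM expression ratio — a proxy for the fraction
     of glycolytic flux leaving pyruvate kinase into the TCA cycle via
     pyruvate dehydrogenase — has a lower median in cases than controls.

Both criteria are scale-free: multiplying all linear expression by a
common constant changes neither fold changes nor ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from warburgph.core_io import ExpressionMatrix, ValidationError

WARBURG_FC = 2.0

LDH_GENES = ("LDHA", "LDHB")
MCT_GENES = ("SLC16A1", "SLC16A3")
FLUX_NUMERATOR = "PDHB"
FLUX_DENOMINATOR = "PKM"


@dataclass
class WarburgVerdict:
    fc_LDHA: float
    fc_LDHB: float
    fc_SLC16A1: float
    fc_SLC16A3: float
    criterion_i: bool
    ratio_case: float  # median per-sample PDHB/PKM over cases
    ratio_control: float
    criterion_ii: bool
    verdict: bool
    ratio_p_value: float | None = None
    n_ratio_excluded: int = 0

    def __post_init__(self) -> None:
        if self.verdict != (self.criterion_i and self.criterion_ii):
            raise ValidationError("verdict must equal criterion_i AND criterion_ii")


def _linear_fc(mat: ExpressionMatrix, gene: str) -> float:
    """2**(difference of log2 group means); NaN if the gene is absent."""
    if gene not in mat.values.index:
        return float("nan")
    row = mat.values.loc[gene]
    return float(
        2.0 ** (row[mat.case_samples].mean() - row[mat.control_samples].mean())
    )


def classify_warburg(
    mat: ExpressionMatrix,
    significance_gate: bool = False,
    ratio_of_group_means: bool = False,
    alpha: float = 0.05,
) -> WarburgVerdict:
    """Apply both criteria to a case/control matrix.

    Parameters
    ----------
    mat
        Must contain LDHA/LDHB, SLC16A1/SLC16A3, PDHB and PKM.
    significance_gate
        If True, criterion (ii) additionally requires a rank-sum test on
        the per-sample ratios to reject at ``alpha`` (off by default; the
        base rule is a strict decrease of the median).
    ratio_of_group_means
        If True, criterion (ii) compares the ratio of linear group means
        instead of the median per-sample ratio.
    """
    mat.require_two_groups()
    needed = set(LDH_GENES) | set(MCT_GENES) | {FLUX_NUMERATOR, FLUX_DENOMINATOR}
    missing = needed - set(mat.values.index)
    if missing:
        raise ValidationError(f"classifier genes missing from matrix: {sorted(missing)}")

    fc = {g: _linear_fc(mat, g) for g in (*LDH_GENES, *MCT_GENES)}
    criterion_i = (fc["LDHA"] > WARBURG_FC or fc["LDHB"] > WARBURG_FC) and (
        fc["SLC16A1"] > WARBURG_FC or fc["SLC16A3"] > WARBURG_FC
    )

    lin = mat.linear()
    pdhb = lin.loc[FLUX_NUMERATOR]
    pkm = lin.loc[FLUX_DENOMINATOR]
    valid = pkm > 0
    n_excluded = int((~valid).sum())
    if not valid.any():
        raise ValidationError("PKM is zero in every sample; flux ratio undefined")
    ratio = (pdhb[valid] / pkm[valid]).astype(float)
    case_ids = [s for s in mat.case_samples if valid[s]]
    ctrl_ids = [s for s in mat.control_samples if valid[s]]
    if not case_ids or not ctrl_ids:
        raise ValidationError("flux ratio undefined in an entire group")

    if ratio_of_group_means:
        r_case = float(pdhb[case_ids].mean() / pkm[case_ids].mean())
        r_ctrl = float(pdhb[ctrl_ids].mean() / pkm[ctrl_ids].mean())
    else:
        r_case = float(np.median(ratio[case_ids]))
        r_ctrl = float(np.median(ratio[ctrl_ids]))
    criterion_ii = r_case < r_ctrl

    p_ratio = None
    if significance_gate:
        p_ratio = float(
            stats.mannwhitneyu(
                ratio[case_ids], ratio[ctrl_ids], alternative="less"
            ).pvalue
        )
        criterion_ii = criterion_ii and p_ratio < alpha

    return WarburgVerdict(
        fc_LDHA=fc["LDHA"],
        fc_LDHB=fc["LDHB"],
        fc_SLC16A1=fc["SLC16A1"],
        fc_SLC16A3=fc["SLC16A3"],
        criterion_i=bool(criterion_i),
        ratio_case=r_case,
        ratio_control=r_ctrl,
        criterion_ii=bool(criterion_ii),
        verdict=bool(criterion_i and criterion_ii),
        ratio_p_value=p_ratio,
        n_ratio_excluded=n_excluded,
    )
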