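"""Fenton-reaction presence criterion from marker gene expression.

Persistent cytosolic Fenton chemistry (Fe2+-catalyzed Haber-Weiss:
O2.- + H2O2 -> .OH + OH- + O2) is inferred when transcriptomic proxies of
the two sides of the reaction co-vary across samples.  The product side
[.OH] is read out through hydroxyl-radical damage response — proteasome
(PSM) gene expression; the substrate side pools proxies of [H2O2]
(TXN, TXN2, GCLC, GCLM), iron uptake [Fe2+] (TFRC, TFR2) and, when the
user supplies one, a superoxide [O2.-] marker set.  Each side is
summarized by the oriented first principal component of its standardized
submatrix, and the criterion is a significantly positive Pearson
correlation between the two scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from warburgph.core_io import ExpressionMatrix, GeneSet, ValidationError

#: a minimal proteasome marker set; users should supply the full PSM list
DEFAULT_OH_PROXY = ("PSMA1", "PSMA2", "PSMB1", "PSMB2", "PSMC1", "PSMD1")
DEFAULT_H2O2_PROXY = ("TXN", "TXN2", "GCLC", "GCLM")
DEFAULT_IRON_PROXY = ("TFRC", "TFR2")

FENTON_P_THRESHOLD = 0.01


@dataclass
class FentonMarkerConfig:
    """Marker gene sets for the four reaction quantities.

    ``superoxide_proxy`` has no default: supply it or the substrate side
    is built from the H2O2 and iron proxies only (flagged in the verdict).
    All supplied sets must be non-empty and pairwise disjoint.
    """

    oh_proxy: GeneSet = field(
        default_factory=lambda: GeneSet.from_iterable("oh_proxy", DEFAULT_OH_PROXY)
    )
    h2o2_proxy: GeneSet = field(
        default_factory=lambda: GeneSet.from_iterable("h2o2_proxy", DEFAULT_H2O2_PROXY)
    )
    iron_proxy: GeneSet = field(
        default_factory=lambda: GeneSet.from_iterable("iron_proxy", DEFAULT_IRON_PROXY)
    )
    superoxide_proxy: GeneSet | None = None

    def __post_init__(self) -> None:
        sets = [self.oh_proxy, self.h2o2_proxy, self.iron_proxy]
        if self.superoxide_proxy is not None:
            sets.append(self.superoxide_proxy)
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                overlap = a.members & b.members
                if overlap:
                    raise ValidationError(
                        f"marker sets {a.name!r} and {b.name!r} overlap: {sorted(overlap)}"
                    )

    def substrate_genes(self) -> frozenset[str]:
        genes = self.h2o2_proxy.members | self.iron_proxy.members
        if self.superoxide_proxy is not None:
            genes = genes | self.superoxide_proxy.members
        return genes


@dataclass
class FentonVerdict:
    lhs_score: np.ndarray  # substrate side per sample
    rhs_score: np.ndarray  # product (.OH) side per sample
    statistic: float  # Pearson r between the sides
    p_value: float
    predicted: bool
    superoxide_missing: bool = False

    def __post_init__(self) -> None:
        if self.predicted and not (self.statistic > 0 and self.p_value < 1.0):
            raise ValidationError("predicted requires a positive, significant correlation")


def _oriented_pc1(sub: np.ndarray) -> np.ndarray:
    """PC1 scores of a samples x genes submatrix, genes standardized,
    oriented to correlate positively with the set's mean expression."""
    sd = sub.std(axis=0, ddof=1)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    z = (sub - sub.mean(axis=0, keepdims=True)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0.0:
        raise ValidationError("marker submatrix has zero variance")
    score = u[:, 0] * s[0]
    mean_expr = sub.mean(axis=1)
    if np.std(mean_expr) > 0 and np.corrcoef(score, mean_expr)[0, 1] < 0:
        score = -score
    return score


def _present(mat: ExpressionMatrix, genes: frozenset[str], label: str) -> list[str]:
    present = sorted(genes & set(mat.values.index))
    if len(present) < 2:
        raise ValidationError(f"fewer than 2 {label} marker genes present in the matrix")
    return present


def assess_fenton(
    mat: ExpressionMatrix,
    cfg: FentonMarkerConfig | None = None,
    threshold: float = FENTON_P_THRESHOLD,
) -> FentonVerdict:
    """Decide whether the dataset shows the Fenton-reaction signature.

    predicted iff Pearson r(product score, substrate score) > 0 with
    two-sided p below ``threshold`` (default 0.01).
    """
    cfg = cfg or FentonMarkerConfig()
    if mat.values.shape[1] < 10:
        raise ValidationError("need at least 10 samples")
    oh_genes = _present(mat, cfg.oh_proxy.members, "product-side")
    sub_genes = _present(mat, cfg.substrate_genes(), "substrate-side")
    rhs = _oriented_pc1(mat.values.loc[oh_genes].to_numpy().T)
    lhs = _oriented_pc1(mat.values.loc[sub_genes].to_numpy().T)
    r, p = stats.pearsonr(lhs, rhs)
    return FentonVerdict(
        lhs_score=lhs,
        rhs_score=rhs,
        statistic=float(r),
        p_value=float(p),
        predicted=bool(r > 0 and p < threshold),
        superoxide_missing=cfg.superoxide_proxy is None,
    )


def fenton_transporter_coupling(
    mat: ExpressionMatrix,
    panel,
    cfg: FentonMarkerConfig | None = None,
) -> pd.DataFrame:
    """Pearson r of each transporter-panel gene with the product-side score.

    A positive loader / negative extruder pattern couples the transporter
    program to the Fenton readout.  Panel genes inside the product proxy
    are rejected (the score would correlate with itself); absent genes are
    recorded with NaN.
    """
    cfg = cfg or FentonMarkerConfig()
    oh_genes = _present(mat, cfg.oh_proxy.members, "product-side")
    clash = set(panel.gene_symbols()) & set(oh_genes)
    if clash:
        raise ValidationError(f"panel genes inside the product proxy: {sorted(clash)}")
    score = _oriented_pc1(mat.values.loc[oh_genes].to_numpy().T)
    rows = []
    for gene in panel.gene_symbols():
        role = panel.role_of(gene)
        if gene in mat.values.index:
            x = mat.values.loc[gene].to_numpy()
            if np.std(x) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, score)
        else:
            r, p = np.nan, np.nan
        rows.append((gene, role, r, p))
    df = pd.DataFrame(rows, columns=["gene", "role", "pearson_r", "p_value"])
    return df.sort_values(["role", "gene"], kind="mergesort").set_index("gene")
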