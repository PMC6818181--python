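"""Gene-set correlation statistics.

Three procedures quantify how a gene or gene set co-varies with another
gene set across samples:

* **PC regression** — when the first two principal components of the
  set's expression submatrix explain at least 75% of its variance, the
  query gene is regressed on them (e_g = b0 + b1*PC1 + b2*PC2) and the
  fit is summarized by R^2 with an F-test p-value.
* **Overlap test** — otherwise the query gene is correlated against every
  background gene, significantly correlated genes are selected by BH-FDR
  at alpha, and the overlap m of the n selected genes with the M-gene set
  is scored by the upper hypergeometric tail
  P = 1 - sum_{i<m} C(M,i) C(N-M,n-i) / C(N,n).
* **Principal-curve correlation** — each set's sample cloud is summarized
  by arc-length projections onto a fitted one-dimensional principal
  curve; the Pearson correlation between the two projection vectors
  measures set-vs-set co-variation, capturing nonlinear within-set
  structure that a single PC would miss.

The same hypergeometric tail drives generic gene-set enrichment against a
user-supplied GMT library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from warburgph.core_io import ExpressionMatrix, GeneSet, ValidationError

PC_VARIANCE_GATE = 0.75
SELECTION_ALPHA = 0.01
DEFAULT_BACKGROUND_N = 20_000  # human-genome background size for enrichment


@dataclass
class CorrelationReport:
    """Result of one correlation procedure with method provenance."""

    method: str  # pc_regression | overlap_test | principal_curve
    # pc_regression
    variance_explained: Optional[float] = None
    coefficients: Optional[tuple[float, float, float]] = None  # (b0, b1, b2)
    r_squared: Optional[float] = None
    p_value: Optional[float] = None
    # overlap_test
    N: Optional[int] = None
    M: Optional[int] = None
    n: Optional[int] = None
    m: Optional[int] = None
    P: Optional[float] = None
    degenerate: bool = False
    # principal_curve
    projections: Optional[tuple[np.ndarray, np.ndarray]] = None
    pcc: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.P is not None and not 0.0 <= self.P <= 1.0 + 1e-12:
            raise ValidationError("tail probability outside [0, 1]")
        if self.m is not None and self.m > min(self.n, self.M):
            raise ValidationError("overlap m exceeds min(n, M)")
        if self.variance_explained is not None and not 0.0 <= self.variance_explained <= 1.0 + 1e-9:
            raise ValidationError("variance explained outside [0, 1]")
        if self.pcc is not None and not -1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12:
            raise ValidationError("PCC outside [-1, 1]")


# ---------------------------------------------------------------------------
# PC regression (gene vs set)
# ---------------------------------------------------------------------------

def _set_pcs(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """PC scores of a samples x genes submatrix (genes centered).

    Returns (PC1 scores, PC2 scores, variance fraction of PC1+PC2).
    With a rank-1 submatrix PC2 is a zero vector and the fraction is 1.
    """
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise ValidationError("set submatrix has zero variance")
    pc1 = u[:, 0] * s[0]
    pc2 = u[:, 1] * s[1] if len(s) > 1 else np.zeros_like(pc1)
    frac = float((s[0] ** 2 + (s[1] ** 2 if len(s) > 1 else 0.0)) / total)
    return pc1, pc2, frac


def gene_vs_set_correlation(
    gene: str,
    gene_set: GeneSet,
    mat: ExpressionMatrix,
    variance_gate: float = PC_VARIANCE_GATE,
    alpha: float = SELECTION_ALPHA,
) -> CorrelationReport:
    """Correlate one gene with a gene set.

    Takes the PC-regression branch when PC1+PC2 of the set's submatrix
    explain at least ``variance_gate`` of its variance; otherwise falls
    back to the selection/overlap test.  The query gene must not belong
    to the set (self-correlation is undefined).
    """
    if gene in gene_set.members:
        raise ValidationError(f"{gene} belongs to the set; self-correlation undefined")
    if gene not in mat.values.index:
        raise ValidationError(f"{gene} absent from matrix")
    members = sorted(m for m in gene_set.members if m in mat.values.index)
    if len(members) < 3:
        raise ValidationError("need at least 3 set members present in the matrix")
    if mat.values.shape[1] < 10:
        raise ValidationError("need at least 10 samples")

    sub = mat.values.loc[members].to_numpy().T  # samples x genes
    try:
        pc1, pc2, frac = _set_pcs(sub)
    except ValidationError:
        return overlap_test(gene, gene_set, mat, alpha=alpha)
    if frac < variance_gate:
        return overlap_test(gene, gene_set, mat, alpha=alpha)

    y = mat.values.loc[gene].to_numpy()
    X = np.column_stack([np.ones_like(pc1), pc1, pc2])
    # drop the PC2 column when it is identically zero (rank-1 set)
    use_pc2 = np.any(pc2 != 0.0)
    beta, *_ = np.linalg.lstsq(X if use_pc2 else X[:, :2], y, rcond=None)
    fitted = (X if use_pc2 else X[:, :2]) @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    k = 2 if use_pc2 else 1  # predictors
    dof = len(y) - k - 1
    if dof <= 0 or 1.0 - r2 <= 0.0:
        p = 0.0 if r2 > 0 else 1.0
    else:
        f_stat = (r2 / k) / ((1.0 - r2) / dof)
        p = float(stats.f.sf(f_stat, k, dof))
    b0 = float(beta[0])
    b1 = float(beta[1])
    b2 = float(beta[2]) if use_pc2 else 0.0
    return CorrelationReport(
        method="pc_regression",
        variance_explained=min(frac, 1.0),
        coefficients=(b0, b1, b2),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        p_value=p,
        notes={"n_members_used": len(members)},
    )


# ---------------------------------------------------------------------------
# Selection + hypergeometric overlap (Eq.-2-style tail)
# ---------------------------------------------------------------------------

def hypergeometric_tail(N: int, M: int, n: int, m: int) -> float:
    """Upper tail P(X >= m) for X ~ Hypergeometric(N, M, n).

    This is 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n), the
    probability of drawing at least m set members when n genes are chosen
    from a background of N containing M set members.
    """
    if M > N or n > N:
        raise ValidationError("set or selection larger than background")
    if m < 0 or m > min(n, M):
        raise ValidationError("overlap m outside [0, min(n, M)]")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def _pearson_vs_all(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of y against every row of X (vectorized)."""
    ns = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(yc**2) * np.sum(Xc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -0.999999999999, 0.999999999999)
    t = r * np.sqrt((ns - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), ns - 2)
    return r, p


def overlap_test(
    gene: str,
    gene_set: GeneSet,
    mat: ExpressionMatrix,
    alpha: float = SELECTION_ALPHA,
) -> CorrelationReport:
    """Select genes correlated with ``gene`` (BH at ``alpha``) and score the
    overlap of the selection with the set by the upper hypergeometric tail."""
    if gene not in mat.values.index:
        raise ValidationError(f"{gene} absent from matrix")
    background = [g for g in mat.values.index if g != gene]
    N = len(background)
    members = frozenset(gene_set.members) & frozenset(background)
    M = len(members)
    if M == 0:
        raise ValidationError("no set member in the background")
    y = mat.values.loc[gene].to_numpy()
    X = mat.values.loc[background].to_numpy()
    _, pvals = _pearson_vs_all(y, X)
    selected_mask = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    selection = {g for g, keep in zip(background, selected_mask) if keep}
    n = len(selection)
    m = len(selection & members)
    if n == 0:
        return CorrelationReport(
            method="overlap_test", N=N, M=M, n=0, m=0, P=1.0, degenerate=True
        )
    P = hypergeometric_tail(N, M, n, m)
    return CorrelationReport(method="overlap_test", N=N, M=M, n=n, m=m, P=P)


def enrich_genesets(
    query: GeneSet | frozenset[str] | set[str],
    library: list[GeneSet],
    N: int = DEFAULT_BACKGROUND_N,
    top_k: int | None = 100,
) -> pd.DataFrame:
    """Rank library sets by hypergeometric enrichment of the query genes.

    Returns a table (set name indexed) with M, n, m, P and BH q, sorted
    ascending by P; ``top_k`` keeps the most enriched sets (default 100).
    An empty query gives P = 1 everywhere.
    """
    if not library:
        raise ValidationError("empty gene-set library")
    members = query.members if isinstance(query, GeneSet) else frozenset(query)
    n = len(members)
    rows = []
    for gs in library:
        M = len(gs.members)
        m = len(members & gs.members)
        P = 1.0 if n == 0 else hypergeometric_tail(N, M, min(n, N), min(m, min(n, M)))
        rows.append((gs.name, M, n, m, P))
    df = pd.DataFrame(rows, columns=["set", "M", "n", "m", "P"]).set_index("set")
    df["q"] = multipletests(df["P"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["P", "m"], ascending=[True, False], kind="mergesort")
    if top_k is not None:
        df = df.head(top_k)
    return df


# ---------------------------------------------------------------------------
# Principal curves (set vs set)
# ---------------------------------------------------------------------------

def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's nearest location on the polyline."""
    seg_start = curve[:-1]
    seg_vec = curve[1:] - seg_start
    seg_len2 = np.sum(seg_vec**2, axis=1)
    seg_len2[seg_len2 == 0.0] = 1e-300
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(np.sum(seg_vec**2, axis=1)))])
    lam = np.empty(len(points))
    for i, x in enumerate(points):
        t = np.clip(np.sum((x - seg_start) * seg_vec, axis=1) / seg_len2, 0.0, 1.0)
        feet = seg_start + t[:, None] * seg_vec
        d2 = np.sum((x - feet) ** 2, axis=1)
        j = int(np.argmin(d2))
        lam[i] = cum[j] + t[j] * np.sqrt(seg_len2[j])
    return lam


def principal_curve(
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    frac: float = 0.6,
) -> np.ndarray:
    """Arc-length projections of samples onto a fitted principal curve.

    Iterative projection/smoothing: the curve starts as the first
    principal component, each coordinate is lowess-smoothed against the
    current arc-length parameter, and samples are re-projected onto the
    smoothed polyline until the mean projection displacement (relative to
    the parameter range) falls below ``tol``, stops shrinking (the
    iteration typically settles into a small oscillation rather than a
    strict fixed point), or ``max_iter`` is reached.

    Parameters
    ----------
    X
        samples x dims data cloud (the expression submatrix of one set,
        samples as rows).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 3:
        raise ValidationError("need a samples x dims matrix with >=3 samples")
    center = X.mean(axis=0)
    Xc = X - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] == 0.0:
        raise ValidationError("degenerate cloud: zero variance")
    lam = Xc @ vt[0]
    prev_shift = np.inf
    for _ in range(max_iter):
        order = np.argsort(lam, kind="mergesort")
        lam_sorted = lam[order]
        # jitter exact ties so the smoother sees distinct abscissae
        if lam_sorted[-1] == lam_sorted[0]:
            break
        fitted = np.empty_like(Xc)
        for d in range(X.shape[1]):
            sm = lowess(
                Xc[order, d], lam_sorted, frac=frac, it=0, return_sorted=False
            )
            fitted[order, d] = sm
        curve = fitted[order]
        # collapse duplicate consecutive curve points
        keep = np.concatenate([[True], np.any(np.diff(curve, axis=0) != 0.0, axis=1)])
        curve = curve[keep]
        if len(curve) < 2:
            break
        new_lam = _project_to_polyline(Xc, curve)
        span = np.ptp(lam) or 1.0
        shift = (
            float(np.mean(np.abs((new_lam - new_lam.mean()) - (lam - lam.mean())))) / span
        )
        lam = new_lam
        if shift < tol or shift >= prev_shift:
            break
        prev_shift = shift
    return lam


def set_vs_set_correlation(
    set_a: GeneSet,
    set_b: GeneSet,
    mat: ExpressionMatrix,
    frac: float = 0.6,
) -> CorrelationReport:
    """Correlate two gene sets through their principal-curve projections.

    Shared genes are removed from both sets first.  Each set's samples x
    genes submatrix is summarized by arc-length projections (DP) onto its
    principal curve; each curve's orientation is fixed so DP correlates
    positively with the set's per-sample mean expression; the report
    carries PCC(DP_a, DP_b) and its two-sided p-value.
    """
    shared = set_a.members & set_b.members
    a_genes = sorted((set_a.members - shared) & set(mat.values.index))
    b_genes = sorted((set_b.members - shared) & set(mat.values.index))
    if len(a_genes) < 2 or len(b_genes) < 2:
        raise ValidationError("each set needs >=2 unshared genes present in the matrix")
    if mat.values.shape[1] < 10:
        raise ValidationError("need at least 10 samples")

    dps = []
    for genes in (a_genes, b_genes):
        sub = mat.values.loc[genes].to_numpy().T  # samples x genes
        lam = principal_curve(sub, frac=frac)
        mean_expr = sub.mean(axis=1)
        if np.std(lam) > 0 and np.std(mean_expr) > 0:
            if np.corrcoef(lam, mean_expr)[0, 1] < 0:
                lam = lam.max() - lam
        dps.append(lam)
    dp1, dp2 = dps
    if np.std(dp1) == 0 or np.std(dp2) == 0:
        raise ValidationError("degenerate projections: zero variance")
    r, p = stats.pearsonr(dp1, dp2)
    return CorrelationReport(
        method="principal_curve",
        projections=(dp1, dp2),
        pcc=float(r),
        p_value=float(p),
        notes={"n_genes_a": len(a_genes), "n_genes_b": len(b_genes), "n_shared_removed": len(shared)},
    )
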