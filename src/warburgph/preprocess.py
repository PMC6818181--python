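"""Expressed-gene calling and probe handling.

Bulk log2 expression pooled over all genes and samples of a dataset is
bimodal: a low mode of genes that are not expressed and a high mode of
expressed genes.  The expressed/not-expressed cut is placed at the lowest
point of the valley between the two peaks of a kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from warburgph.core_io import ExpressionMatrix, ValidationError


class NoValleyError(ValueError):
    """The pooled density has no interior minimum between two modes.

    Raised for unimodal data; callers may fall back to a manual threshold.
    """


@dataclass
class ExpressionThreshold:
    """A dataset-level expressed/not-expressed cut with its derivation trace."""

    threshold_value: float
    peak_low: float
    peak_high: float
    bandwidth: float
    density_grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if not self.peak_low < self.threshold_value < self.peak_high:
            raise ValidationError("threshold must lie strictly between the two peaks")

    def is_expressed(self, values: np.ndarray) -> np.ndarray:
        """Genes at or below the valley are called not expressed."""
        return np.asarray(values) > self.threshold_value


def _local_maxima(y: np.ndarray) -> np.ndarray:
    interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    idx = np.flatnonzero(interior) + 1
    # grid endpoints can also be modes when the density is cut off
    if y[0] > y[1]:
        idx = np.concatenate([[0], idx])
    if y[-1] > y[-2]:
        idx = np.concatenate([idx, [len(y) - 1]])
    return idx


def find_expression_threshold(
    mat: ExpressionMatrix | np.ndarray,
    grid_points: int = 512,
    bw_method: str = "silverman",
) -> ExpressionThreshold:
    """Find the valley of the pooled log2 expression density.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a regular grid
    spanning the data range; the two highest local maxima are taken as the
    not-expressed and expressed modes and the threshold is the density
    minimum between them.  The result is invariant to gene and sample
    order since all values are pooled.
    """
    if isinstance(mat, ExpressionMatrix):
        pooled = mat.values.to_numpy().ravel()
    else:
        pooled = np.asarray(mat, dtype=float).ravel()
    if pooled.size < 200:
        raise ValidationError("need at least 200 pooled values for density estimation")
    kde = gaussian_kde(pooled, bw_method=bw_method)
    grid = np.linspace(pooled.min(), pooled.max(), grid_points)
    dens = kde(grid)
    peaks = _local_maxima(dens)
    if len(peaks) < 2:
        raise NoValleyError("pooled density is unimodal; supply a manual threshold")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        raise NoValleyError("the two dominant modes are adjacent; no interior valley")
    valley = lo + 1 + int(np.argmin(dens[lo + 1 : hi]))
    return ExpressionThreshold(
        threshold_value=float(grid[valley]),
        peak_low=float(grid[lo]),
        peak_high=float(grid[hi]),
        bandwidth=float(kde.factor * pooled.std(ddof=1)),
        density_grid=grid,
        density=dens,
    )


def expressed_mask(mat: ExpressionMatrix, threshold: ExpressionThreshold | float) -> pd.Series:
    """Per-gene expressed call: mean expression above the valley in either group.

    A gene below the cut in both groups is flagged not expressed and is
    excluded from differential testing.
    """
    cut = threshold.threshold_value if isinstance(threshold, ExpressionThreshold) else float(threshold)
    mat.require_two_groups()
    mean_case = mat.values[mat.case_samples].mean(axis=1)
    mean_ctrl = mat.values[mat.control_samples].mean(axis=1)
    return (mean_case > cut) | (mean_ctrl > cut)


def collapse_probes(
    mat: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Collapse a probe-level matrix to one row per gene.

    For a gene measured by several probes the probe with the highest mean
    expression across all samples represents it; ties break to the
    lexicographically smallest probe id.  Probes absent from the map are
    dropped and counted.  Retained rows are carried over bit-exactly.
    """
    unmapped = [p for p in mat.values.index if p not in probe_to_gene]
    mapped = mat.values.drop(index=unmapped)
    if mapped.empty:
        raise ValidationError("no probe maps to a gene")
    means = mapped.mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(mapped.index):  # lexicographic scan makes the tie-break explicit
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    collapsed = mapped.loc[[best[g] for g in genes]]
    collapsed.index = genes
    out = ExpressionMatrix(
        values=collapsed,
        sample_groups=dict(mat.sample_groups),
        platform=mat.platform,
        paired=mat.paired,
    )
    return out, {"probes_in": int(len(mat.values)), "probes_unmapped": int(len(unmapped)), "genes_out": int(len(genes))}
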