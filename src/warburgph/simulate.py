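"""Seeded synthetic expression data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a bimodal marginal distribution of log2 expression (a low
"not expressed" mode and a high "expressed" mode), case/control groups with
additive log2 fold-change shifts planted on named genes, latent Gaussian
factors that induce a chosen correlation between gene groups, and an
activation time course with rising / falling / peak-then-decline trends.

Expression for an expressed gene in sample s is

    x_gs = mu_high + sqrt(rho) * sigma * f_s + sqrt(1 - rho) * sigma * e_gs
           [+ log2(FC_g) if s is a case sample]

where f_s is the latent factor shared by all genes in a linked group and
e_gs is iid N(0, 1) noise, so any two genes sharing a factor have
population correlation rho and every marginal stays N(mu_high, sigma^2).
Genes outside any link take the rho = 0 form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from warburgph.core_io import CASE, CONTROL, ExpressionMatrix, ValidationError

Trend = Literal["rising", "falling", "peak_then_decline"]


@dataclass(frozen=True)
class LatentLink:
    """Two gene groups tied to one shared factor with correlation ``rho``."""

    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    rho: float

    def genes(self) -> tuple[str, ...]:
        return tuple(self.set_a) + tuple(self.set_b)


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the structure of the real datasets the analysis was
    designed for: log2-scale expression with a non-expressed mode near 0
    and an expressed mode near 6 (both sd 1), a third of genes silent, and
    a 19-point / 20-minute-interval activation time course when requested.
    """

    n_genes: int = 200
    n_case: int = 50
    n_control: int = 50
    seed: int = 0
    nonexpressed_fraction: float = 1.0 / 3.0
    mode_low: tuple[float, float] = (0.0, 1.0)  # (mean, sd) of silent log2 peak
    mode_high: tuple[float, float] = (6.0, 1.0)  # (mean, sd) of expressed log2 peak
    planted_fc: dict[str, float] = field(default_factory=dict)  # gene -> linear FC
    latent_links: list[LatentLink] = field(default_factory=list)
    n_timepoints: int = 19
    timepoint_minutes: float = 20.0
    trends: dict[str, Trend] = field(default_factory=dict)
    trend_amplitude: float = 2.0  # total log2 swing of a trending gene
    timecourse_noise_sd: float = 0.25

    def validate(self) -> None:
        if self.mode_low[0] >= self.mode_high[0]:
            raise ValidationError("mode_low mean must be below mode_high mean")
        if not 0.0 <= self.nonexpressed_fraction < 1.0:
            raise ValidationError("nonexpressed_fraction must be in [0, 1)")
        for g, fc in self.planted_fc.items():
            if fc <= 0:
                raise ValidationError(f"planted fold change for {g} must be positive")
        seen: dict[str, float] = {}
        for link in self.latent_links:
            if not -1.0 <= link.rho <= 1.0:
                raise ValidationError("latent link rho must lie in [-1, 1]")
            for g in link.genes():
                if g in seen and seen[g] != link.rho:
                    raise ValidationError(
                        f"gene {g} appears in latent links with contradictory rho"
                    )
                seen[g] = link.rho


@dataclass
class GroundTruth:
    """What was planted, for checking recovery downstream."""

    expressed_genes: list[str]
    nonexpressed_genes: list[str]
    planted_log2fc: dict[str, float]
    latent_links: list[LatentLink]


def _gene_names(spec: SimulationSpec) -> tuple[list[str], list[str]]:
    """Named genes (planted / linked / trending) first, then filler ids."""
    named: list[str] = []
    for g in spec.planted_fc:
        if g not in named:
            named.append(g)
    for link in spec.latent_links:
        for g in link.genes():
            if g not in named:
                named.append(g)
    for g in spec.trends:
        if g not in named:
            named.append(g)
    n_filler = spec.n_genes - len(named)
    if n_filler < 0:
        raise ValidationError("n_genes smaller than the number of named genes")
    filler = [f"G{i:05d}" for i in range(n_filler)]
    return named, filler


def simulate_dataset(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one dataset; deterministic given ``spec.seed``.

    Named genes (those carrying a planted fold change or a latent link) are
    always expressed; the non-expressed fraction is taken from the filler
    genes so planted structure is never silenced.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    named, filler = _gene_names(spec)
    genes = named + filler
    n_samples = spec.n_case + spec.n_control
    sample_ids = [f"case_{i:03d}" for i in range(spec.n_case)] + [
        f"ctrl_{i:03d}" for i in range(spec.n_control)
    ]
    groups = {s: (CASE if s.startswith("case_") else CONTROL) for s in sample_ids}

    n_silent = min(int(round(spec.nonexpressed_fraction * len(genes))), len(filler))
    silent = set(filler[len(filler) - n_silent :])

    mu_lo, sd_lo = spec.mode_low
    mu_hi, sd_hi = spec.mode_high
    values = np.empty((len(genes), n_samples))

    factor_of_gene: dict[str, int] = {}
    rho_of_gene: dict[str, float] = {}
    factors = rng.standard_normal((len(spec.latent_links), n_samples))
    for k, link in enumerate(spec.latent_links):
        for g in link.genes():
            factor_of_gene[g] = k
            rho_of_gene[g] = link.rho

    for i, g in enumerate(genes):
        if g in silent:
            values[i] = rng.normal(mu_lo, sd_lo, n_samples)
            continue
        rho = abs(rho_of_gene.get(g, 0.0))
        noise = rng.standard_normal(n_samples)
        row = mu_hi + sd_hi * np.sqrt(1.0 - rho) * noise
        if g in factor_of_gene:
            sign = 1.0 if rho_of_gene[g] >= 0 or g in spec.latent_links[factor_of_gene[g]].set_a else -1.0
            row = row + sign * sd_hi * np.sqrt(rho) * factors[factor_of_gene[g]]
        if g in spec.planted_fc:
            row[: spec.n_case] += np.log2(spec.planted_fc[g])
        values[i] = row

    mat = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        sample_groups=groups,
        paired=False,
    )
    truth = GroundTruth(
        expressed_genes=[g for g in genes if g not in silent],
        nonexpressed_genes=sorted(silent),
        planted_log2fc={g: float(np.log2(fc)) for g, fc in spec.planted_fc.items()},
        latent_links=list(spec.latent_links),
    )
    return mat, truth


# ---------------------------------------------------------------------------
# Canonical planted scenarios
# ---------------------------------------------------------------------------

_CLASSIFIER_GENES = ("LDHA", "LDHB", "SLC16A1", "SLC16A3", "PDHB", "PKM")
_LOADERS = ("SLC4A1AP", "SLC4A2", "SLC4A3", "SLC26A6", "ATP6V0B", "ATP6V0C")
_EXTRUDERS = ("SLC4A4", "SLC4A9", "SLC9A2", "SLC9A3", "SLC9A4", "SLC9A9", "SLC26A9")
_PSM = ("PSMA1", "PSMA2", "PSMB1", "PSMB2", "PSMC1", "PSMD1")
_SUBSTRATE = ("TXN", "TXN2", "GCLC", "GCLM", "TFRC", "TFR2")


def _base_fc() -> dict[str, float]:
    """Neutral fold changes that pin every analysis gene as expressed."""
    genes = _CLASSIFIER_GENES + _LOADERS + _EXTRUDERS + _PSM + _SUBSTRATE
    return {g: 1.0 for g in genes}


def cancer_like_spec(
    seed: int,
    n_case: int = 100,
    n_control: int = 100,
    n_genes: int = 200,
    fenton_rho: float = 0.8,
) -> SimulationSpec:
    """Planted cancer pattern: Warburg fold changes (LDHA x4, SLC16A1 x3,
    PDHB halved so the PDHB/PKM ratio drops), acid loaders up x2 and
    extruders down x2, and a latent factor tying the Fenton product-side
    (proteasome) genes to the substrate-side markers and the loaders."""
    fc = _base_fc()
    fc.update({"LDHA": 4.0, "SLC16A1": 3.0, "PDHB": 0.5})
    fc.update({g: 2.0 for g in _LOADERS})
    fc.update({g: 0.5 for g in _EXTRUDERS})
    links = []
    if fenton_rho != 0.0:
        links.append(LatentLink(set_a=_PSM, set_b=_SUBSTRATE + _LOADERS, rho=fenton_rho))
    return SimulationSpec(
        n_genes=n_genes, n_case=n_case, n_control=n_control, seed=seed,
        planted_fc=fc, latent_links=links,
    )


def npc_like_spec(
    seed: int, n_case: int = 100, n_control: int = 100, n_genes: int = 200
) -> SimulationSpec:
    """Planted proliferating-normal-cell pattern: the Warburg fold changes
    are present but the loaders go down, the extruders stay flat and no
    Fenton latent link is planted."""
    fc = _base_fc()
    fc.update({"LDHA": 4.0, "SLC16A1": 3.0, "PDHB": 0.5})
    fc.update({g: 0.5 for g in _LOADERS})
    return SimulationSpec(
        n_genes=n_genes, n_case=n_case, n_control=n_control, seed=seed, planted_fc=fc
    )


def null_spec(
    seed: int, n_case: int = 100, n_control: int = 100, n_genes: int = 200
) -> SimulationSpec:
    """No planted structure: all analysis genes expressed but unshifted."""
    return SimulationSpec(
        n_genes=n_genes, n_case=n_case, n_control=n_control, seed=seed,
        planted_fc=_base_fc(),
    )


def simulate_timecourse(spec: SimulationSpec) -> pd.DataFrame:
    """Gene x timepoint matrix following each gene's declared trend.

    Timepoints are evenly spaced (default 19 points at 20-minute
    intervals, matching an activation time-course design whose analysis
    drops the time-zero point and groups the remaining 18 into six
    triples).  Trends are linear ramps on log2 scale; ``peak_then_decline``
    ramps up to a peak at the 60% mark and then falls.  Noise sd 0 gives
    the exact noiseless trajectories.
    """
    spec.validate()
    if spec.n_timepoints < 6:
        raise ValidationError("a time course needs at least 6 timepoints")
    if not spec.trends:
        raise ValidationError("no trend declared for any gene")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_timepoints, dtype=float)
    u = t / (spec.n_timepoints - 1)  # 0..1
    base = spec.mode_high[0]
    amp = spec.trend_amplitude
    rows = {}
    for g, trend in spec.trends.items():
        if trend == "rising":
            shape = u
        elif trend == "falling":
            shape = 1.0 - u
        elif trend == "peak_then_decline":
            peak = 0.6
            shape = np.where(u <= peak, u / peak, (1.0 - u) / (1.0 - peak))
        else:
            raise ValidationError(f"unknown trend {trend!r} for gene {g}")
        rows[g] = base + amp * (shape - 0.5) + rng.normal(0.0, spec.timecourse_noise_sd, len(t))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"t{int(i * spec.timepoint_minutes)}min" for i in range(spec.n_timepoints)]
    return df
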