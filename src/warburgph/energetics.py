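"""Proton stoichiometry of ATP pathways and the pH-shift proton budget.

Three reactions fix the ledger:

* respiration synthesis  ADP3- + HPO4^2- -> ATP4- + OH-   (consumes 1 H+/ATP)
* glycolysis synthesis   glucose + 2 ADP3- + 2 HPO4^2- -> 2 lactate + 2 ATP4-
  (pH neutral; 1 lactate per ATP)
* hydrolysis             ATP4- + H2O -> ADP3- + HPO4^2- + H+  (releases 1 H+/ATP)

So a glycolytic ATP releases one net proton over its synthesize-and-spend
cycle while a respiratory ATP is net neutral — respiration-then-spend
moves protons only transiently, which is how accumulating respiratory ATP
raises intracellular pH before proliferation.

The closed-form proton budget for a pH shift multiplies the free-proton
concentration change by cell volume, the cytosolic buffering coefficient
and Avogadro's number:

    n(H+) = (10^-pH_start - 10^-pH_end) [mol/L]
            x volume [um^3] x 1e-15 [L/um^3]
            x buffer_coefficient x N_A
"""

from __future__ import annotations

from dataclasses import dataclass

from warburgph.core_io import ValidationError

ATP_PER_GLUCOSE_RESPIRATION = 36
ATP_PER_GLUCOSE_GLYCOLYSIS = 2

#: per-ATP proton bookkeeping: (H+ consumed at synthesis, H+ released at
#: synthesis, lactate produced at synthesis)
_LEDGER = {
    "respiration_synthesis": (1, 0, 0),
    "glycolysis_synthesis": (0, 0, 1),
}
_HYDROLYSIS_RELEASE = 1  # H+ per ATP hydrolyzed, any provenance

LITER_PER_UM3 = 1e-15
AVOGADRO = 6.02e23  # value used throughout the pH arithmetic


def net_protons(pathway: str, n_atp: int, include_hydrolysis: bool = True) -> int:
    """Net H+ released by synthesizing ``n_atp`` ATPs via ``pathway``
    (negative = net consumption), optionally including their hydrolysis.

    glycolysis + hydrolysis -> +1 per ATP; respiration + hydrolysis -> 0;
    respiration synthesis alone -> -1 per ATP.  Additive in ``n_atp``.
    """
    if pathway not in _LEDGER:
        raise ValidationError(
            f"unknown pathway {pathway!r}; choose from {sorted(_LEDGER)}"
        )
    if n_atp < 0:
        raise ValidationError("n_atp must be non-negative")
    consumed, released, _lactate = _LEDGER[pathway]
    net = released - consumed
    if include_hydrolysis:
        net += _HYDROLYSIS_RELEASE
    return net * n_atp


def lactate_released(pathway: str, n_atp: int) -> int:
    """Lactate molecules produced alongside ``n_atp`` ATPs (glycolysis: 1/ATP)."""
    if pathway not in _LEDGER:
        raise ValidationError(f"unknown pathway {pathway!r}")
    return _LEDGER[pathway][2] * n_atp


@dataclass
class PhShiftSpec:
    """Inputs of the closed-form proton budget.

    Defaults reproduce the canonical scenario: raising a 100 um^3 human
    cell from resting pH 6.8 to the proliferative 7.4 against a cytosolic
    buffering coefficient of 2e5 (the dimensionless amplification of the
    free-proton change by intracellular buffering in this pH range).
    """

    pH_start: float = 6.8
    pH_end: float = 7.4
    volume_um3: float = 100.0
    buffer_coefficient: float = 2e5
    avogadro: float = AVOGADRO
    atp_per_nucleotide: int = 5
    genome_nucleotides: float = 6e9

    def __post_init__(self) -> None:
        for ph in (self.pH_start, self.pH_end):
            if not 0.0 < ph < 14.0:
                raise ValidationError("pH must lie in (0, 14)")
        if self.volume_um3 <= 0 or self.buffer_coefficient <= 0:
            raise ValidationError("volume and buffer coefficient must be positive")


def protons_for_ph_shift(spec: PhShiftSpec | None = None) -> dict:
    """Protons (hence ATPs, one H+ per ATP) to move intracellular pH.

    Returns ``protons`` (negative when pH_end < pH_start, with the
    ``direction`` flag set to "acidify"), plus the equivalent ATP count.
    Linear in volume and buffer coefficient; antisymmetric in the pH
    endpoints.
    """
    spec = spec or PhShiftSpec()
    delta_conc = 10.0 ** (-spec.pH_start) - 10.0 ** (-spec.pH_end)  # mol/L
    protons = (
        delta_conc
        * spec.volume_um3
        * spec.buffer_coefficient
        * LITER_PER_UM3
        * spec.avogadro
    )
    return {
        "protons": protons,
        "atp_equivalent": protons,
        "direction": "alkalinize" if protons >= 0 else "acidify",
        "delta_free_h_mol_per_l": delta_conc,
    }


def genome_fraction_equivalent(protons: float, spec: PhShiftSpec | None = None) -> float:
    """Express an ATP count as a fraction of the genome's synthesis cost.

    fraction = protons / (genome_nucleotides x atp_per_nucleotide); the
    canonical 1.43e9 protons come to ~4.7% (143/3000) of the ~3e10 ATPs a
    full human genome's nucleotides would cost.
    """
    if protons < 0:
        raise ValidationError("protons must be non-negative")
    spec = spec or PhShiftSpec()
    return protons / (spec.genome_nucleotides * spec.atp_per_nucleotide)
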