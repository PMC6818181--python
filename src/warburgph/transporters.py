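"""The curated pH-transporter panel and the net acidification score.

Plasma-membrane transporters whose net effect lowers intracellular pH
(acid loaders: Cl-/HCO3- exchangers, the plasma-membrane V-ATPase
subunits) or raises it (acid extruders: Na+/HCO3- cotransporters,
Na+/H+ exchangers) form the panel; the two monocarboxylate lactate
exporters SLC16A1/3 are carried separately because, being proton-gradient
driven, they cannot by themselves reverse the intra/extracellular pH
gradient and are excluded from the direction score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from warburgph.core_io import ValidationError

ACID_LOADER = "acid_loader"
ACID_EXTRUDER = "acid_extruder"
LACTATE_EXPORTER = "lactate_exporter"


@dataclass
class TransporterPanel:
    """Annotation table: symbol, family, role, included, exclusion_reason."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"symbol", "family", "role", "included", "exclusion_reason"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"panel table missing columns: {sorted(missing)}")
        if self.table["symbol"].duplicated().any():
            raise ValidationError("duplicate symbols in panel")
        excl = self.table[~self.table["included"]]
        if (excl["exclusion_reason"].str.strip() == "").any():
            raise ValidationError("every excluded gene needs an exclusion reason")

    def _included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    def gene_symbols(self) -> list[str]:
        """Symbols of the included panel genes."""
        return list(self._included()["symbol"])

    def by_role(self, role: str) -> list[str]:
        sub = self._included()
        return list(sub.loc[sub["role"] == role, "symbol"])

    @property
    def acid_loaders(self) -> list[str]:
        return self.by_role(ACID_LOADER)

    @property
    def acid_extruders(self) -> list[str]:
        return self.by_role(ACID_EXTRUDER)

    @property
    def lactate_exporters(self) -> list[str]:
        return self.by_role(LACTATE_EXPORTER)

    def role_of(self, symbol: str) -> str:
        row = self.table[self.table["symbol"] == symbol]
        if row.empty:
            raise KeyError(symbol)
        return str(row["role"].iloc[0])


def load_panel(path: str | Path) -> TransporterPanel:
    """Read a panel annotation TSV (editable by users to amend roles)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if df["included"].dtype == object:
        df["included"] = df["included"].map({"True": True, "False": False})
    return TransporterPanel(table=df)


def load_default_panel() -> TransporterPanel:
    """The default curated panel.

    Included: six acid loaders (SLC4A1AP, SLC4A2, SLC4A3, SLC26A6,
    ATP6V0B, ATP6V0C), seven acid extruders (SLC4A4, SLC4A9, SLC9A2/3/4/9,
    SLC26A9) and the two lactate exporters SLC16A1/3.  Family members
    dropped for ambiguous localization, absent expression or non-pH
    function are retained with their exclusion reasons.  ATP6V0B and
    ATP6V0C encode subunits of one V-ATPase complex and carry the same
    expression signal; both stay in the panel and in the score.
    """
    with resources.as_file(resources.files("warburgph").joinpath("data/transporter_panel.tsv")) as p:
        return load_panel(p)


def acidification_summary(result, panel: TransporterPanel) -> dict:
    """Integer tally of the net acidification direction of a dataset.

    score = (#loaders up + #extruders down) - (#loaders down + #extruders up)
    over heatmap calls; positive means the transporter program acidifies
    the cytosol (cancer-like), negative alkalinizes (NPC-like).  Lactate
    exporters never contribute.
    """
    table = result.table if hasattr(result, "table") else result
    loaders = [g for g in panel.acid_loaders if g in table.index]
    extruders = [g for g in panel.acid_extruders if g in table.index]
    if not loaders and not extruders:
        raise ValidationError("no panel gene present in the differential result")
    calls = table["heatmap_call"]
    n_load_up = sum(calls[g] == "up" for g in loaders)
    n_load_down = sum(calls[g] == "down" for g in loaders)
    n_ext_up = sum(calls[g] == "up" for g in extruders)
    n_ext_down = sum(calls[g] == "down" for g in extruders)
    score = (n_load_up + n_ext_down) - (n_load_down + n_ext_up)
    verdict = "acidifying" if score > 0 else ("alkalinizing" if score < 0 else "neutral")
    return {
        "score": int(score),
        "verdict": verdict,
        "loaders_up": int(n_load_up),
        "loaders_down": int(n_load_down),
        "extruders_up": int(n_ext_up),
        "extruders_down": int(n_ext_down),
        "missing": sorted(
            set(panel.acid_loaders + panel.acid_extruders) - set(loaders) - set(extruders)
        ),
    }
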