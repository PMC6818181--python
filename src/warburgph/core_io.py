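"""Domain containers and plain-text readers/writers.

Expression matrices travel as tab-separated tables (genes in rows, samples
in columns, cells on log2 scale); gene sets as GMT lines; reports as JSON
with an explicit parameter echo so every number is traceable to the stage
and settings that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

PLATFORM_RNASEQ = "rnaseq_fpkm_log2"
PLATFORM_MICROARRAY = "microarray_norm"


class FormatError(ValueError):
    """Malformed input file (ragged rows, duplicate ids, bad GMT line)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression on log2 scale with case/control labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids, cells are
        log2-scale normalized expression (log2 FPKM for RNA-seq-like data,
        normalized log intensity for microarray-like data).
    sample_groups
        Label per sample, each ``"case"`` or ``"control"``.
    platform
        ``"rnaseq_fpkm_log2"`` or ``"microarray_norm"``.
    paired
        Whether case and control samples are matched one-to-one (enables
        the signed-rank test downstream).
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    platform: str = PLATFORM_RNASEQ
    paired: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValidationError(f"unlabeled samples: {missing[:5]}")
        bad = {g for g in self.sample_groups.values()} - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValidationError("missing values are not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in_group(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group(CONTROL)

    def require_two_groups(self) -> None:
        if not self.case_samples or not self.control_samples:
            raise ValidationError("comparative operations need non-empty case and control groups")

    def linear(self) -> pd.DataFrame:
        """De-logged expression, 2**x (stored values are log2 scale)."""
        return np.power(2.0, self.values)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[present].copy(),
            sample_groups=dict(self.sample_groups),
            platform=self.platform,
            paired=self.paired,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (|members| is the set size M)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    @staticmethod
    def from_iterable(name: str, members: Iterable[str]) -> "GeneSet":
        return GeneSet(name=name, members=frozenset(members))


@dataclass
class AnalysisReport:
    """Per-stage results of a pipeline run plus the parameters used."""

    dataset_id: str
    parameters: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, Any] = field(default_factory=dict)

    def add_stage(self, name: str, payload: Any) -> None:
        self.stages[name] = payload

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        doc = {
            "dataset_id": self.dataset_id,
            "parameters": self.parameters,
            "stages": self.stages,
        }
        text = json.dumps(doc, indent=indent, default=_jsonify, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if hasattr(obj, "__dataclass_fields__"):
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_expression_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    platform: str = PLATFORM_RNASEQ,
    paired: bool = False,
) -> ExpressionMatrix:
    """Read a rectangular TSV (first column gene ids, header sample ids).

    Every sample column must appear in ``group_map``; unlabeled samples are
    rejected rather than silently dropped.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):  # pandas would mangle these to s1.1 etc.
        raise FormatError(f"{path}: duplicated sample columns")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicated gene rows")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    groups = {str(s): group_map[str(s)] for s in values.columns if str(s) in group_map}
    mat = ExpressionMatrix(
        values=values,
        sample_groups=groups,
        platform=platform,
        paired=paired,
    )
    if not mat.case_samples or not mat.control_samples:
        raise ValidationError(f"{path}: one of the groups is empty")
    return mat


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV plus a sidecar ``<path>.groups.tsv`` label table."""
    path = Path(path)
    mat.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".groups.tsv")
    with open(sidecar, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in mat.sample_ids:
            fh.write(f"{s}\t{mat.sample_groups[s]}\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    The description field is discarded; duplicate members within a line are
    de-duplicated.  A line with fewer than three fields is a format error.
    """
    sets: list[GeneSet] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name, _desc, *members = fields
        members = [m for m in members if m]
        sets.append(GeneSet.from_iterable(name, members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.members)]) + "\n")


def write_categorical_matrix(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a categorical heatmap matrix (values in {up, down, unchanged, not_expressed})."""
    allowed = {"up", "down", "unchanged", "not_expressed", "missing"}
    bad = set(np.unique(calls.values.astype(str))) - allowed
    if bad:
        raise ValidationError(f"illegal categories: {sorted(bad)}")
    calls.to_csv(path, sep="\t", index_label="gene_id")
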